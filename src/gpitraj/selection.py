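"""Atom selection mini-language.

Grammar (keywords are case-sensitive, values are whitespace-separated)::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := not_expr ("and" not_expr)*
    not_expr := "not" not_expr | "(" expr ")" | clause
    clause   := FIELD value+
    FIELD    := name | element | residue_name | residue_seq | chain | role

Multiple values in one clause are OR-ed (``name CA CB`` matches either).
``residue_seq`` accepts single integers and inclusive ranges ``lo:hi`` or
``lo-hi``.  Results are returned as a sorted array of 0-based atom indices;
an empty result is legal.
"""

from __future__ import annotations

import re

import numpy as np

from .errors import SelectionError
from .model import ROLES, Topology

FIELDS = ("name", "element", "residue_name", "residue_seq", "chain", "role")
KEYWORDS = set(FIELDS) | {"and", "or", "not", "(", ")"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _Parser:
    def __init__(self, expression: str, topology: Topology):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.topo = topology

    def fail(self, msg: str, at: int | None = None) -> None:
        if at is None:
            at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expression)
        raise SelectionError(f"{msg} at position {at} in {self.expression!r}")

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            self.fail("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self.fail("empty selection expression", at=0)
        mask = self.or_expr()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() == "and":
            self.take()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.not_expr()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.take()
            return mask
        return self.clause()

    def clause(self) -> np.ndarray:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expression)
        tok = self.take()
        if tok not in FIELDS:
            self.fail(f"expected a field keyword, got {tok!r}", at=at)
        values = []
        while self.peek() is not None and self.peek() not in KEYWORDS:
            values.append(self.take())
        if not values:
            self.fail(f"field {tok!r} needs at least one value")
        return self.match(tok, values, at)

    def match(self, field: str, values: list[str], at: int) -> np.ndarray:
        topo = self.topo
        if field == "name":
            return np.isin(topo.names, values)
        if field == "element":
            return np.isin(topo.elements, [v.upper() for v in values])
        if field == "residue_name":
            return np.isin(topo.residue_names, values)
        if field == "chain":
            return np.isin(topo.chains, values)
        if field == "role":
            mask = np.zeros(topo.n_atoms, dtype=bool)
            for v in values:
                if v not in ROLES:
                    self.fail(f"unknown role {v!r}", at=at)
                mask |= topo.role_masks[v]
            return mask
        # residue_seq: integers and inclusive ranges
        mask = np.zeros(topo.n_atoms, dtype=bool)
        for v in values:
            m = re.fullmatch(r"(-?\d+)(?:[:\-](-?\d+))?", v)
            if m is None:
                self.fail(f"bad residue_seq value {v!r}", at=at)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            mask |= (topo.residue_seqs >= lo) & (topo.residue_seqs <= hi)
        return mask


def select(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression; return sorted 0-based atom indices."""
    mask = _Parser(expression, topology).parse()
    return np.flatnonzero(mask)


def select_one(topology: Topology, expression: str) -> int:
    """Evaluate an expression that must resolve to exactly one atom."""
    idx = select(topology, expression)
    if len(idx) != 1:
        raise SelectionError(
            f"expression {expression!r} resolves to {len(idx)} atoms, expected exactly 1"
        )
    return int(idx[0])
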