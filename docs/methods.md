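# Methods

This note records the models, conventions and numerical choices behind each
analysis, what the synthetic generators do and do not emulate, and the known
limitations.

## Conventions

Lengths are nanometres everywhere inside the package; PDB ångströms are
converted on read and back on write (PDB's three coordinate decimals bound
the round-trip error at 10⁻⁴ nm). Frames and atom indices are 0-based;
`residue_seq` keeps the numbering of the source file so residues can be
referred to the way structural biologists name them. Boxes are orthorhombic
only, and periodic distances use per-axis minimum-image wrapping; triclinic
cells are out of scope. The membrane normal is identified with the +z box
axis — bilayers built by the usual setup tools lie in the xy plane — and no
membrane-plane fitting is attempted.

The PDB reader/writer accepts four-character residue names in columns 18–21
(the CHARMM/VMD lipid convention: DOPC, CHL1, …). Coarse-grain beads are
treated exactly like atoms throughout, so every analysis works identically
on coarse-grained and atomistic input.

## Lipid contacts (dual-cutoff booking)

The per-frame distance between a residue and a lipid molecule is the minimum
over all atom pairs. A contact event opens at the first frame with
d < `lower_cutoff` (default 0.55 nm) and closes at the first frame with
d ≥ `upper_cutoff` (default 1.0 nm); events still open at the trajectory end
are closed there and their truncated duration counted as-is (no censoring
correction — noted in output metadata considerations below). The hysteresis
band means a lipid rattling at the edge of a binding site books as one long
event rather than many short ones; with the two cutoffs equal the rule
degenerates to plain thresholding.

Per residue and species, **occupancy** is 100 × |union of in-contact frames
over the species' molecules| / n_frames, and **residence time** is by
default the mean pooled event duration, which is unambiguous and directly
comparable across systems. An alternative estimator fits the normalised
event-survival curve S(t) with a single exponential (τ) or a double
exponential A·exp(−t/τ₁) + (1−A)·exp(−t/τ₂) (reported as the mixture mean
A·τ₁ + (1−A)·τ₂), selectable with `--residence-estimator survival-exp`;
survival-based estimators are common in lipid-binding tools but depend on
fit choices, so they are not the default. Replicates are pooled with equal
frame weight; a per-replicate table is always written alongside.

Hotspot flagging (occupancy ≥ a AND residence ≥ b) is exposed with
user-supplied thresholds, which should be species-specific: weakly binding
lipids such as cholesterol warrant lower thresholds than phosphatidylcholine.

## Hydrogen bonds

A bond is any donor–hydrogen–acceptor triplet with D–A ≤ `da_cutoff`
(default 3.0 Å) and D–H–A angle (vertex at the hydrogen) ≥ `dha_angle_min`
(default 150°) — the documented defaults of the standard geometric H-bond
analyses; both are flags because different force fields justify different
values. Hydrogens attach to donor heavy atoms by first-frame proximity
(≤ 1.2 Å, nearest donor wins); donors with no resolvable hydrogen are
silently skipped, so coarse-grain input yields zero bonds rather than an
error. Donor/acceptor candidates come from atom-name lookup tables (protein
backbone/side-chain N, O, S; phosphatidylcholine phosphate and ester
oxygens; the cholesterol hydroxyl), restricted by the user's selections, and
both bonding directions (protein donor → lipid acceptor and vice versa) are
counted. The per-residue average is (records attributed to the residue) /
(total frames); attribution is by donor residue by default, with
`--count both` also crediting the acceptor's residue, since published
per-residue bond counts are sometimes donor-only and sometimes symmetric.

## Flexibility

**Tilt.** The tilt of a body axis (two single-atom selections, tail → head —
e.g. the N-terminal to C-terminal backbone nitrogens of an ectodomain, or
the inositol C6 → proximal-mannose C4 vector of a GPI glycan) is
arccos(v·ẑ/|v|), reported unsigned in [0°, 180°], one series per replicate.

**RMSF.** RMSF_i = √⟨‖r_i − ⟨r_i⟩‖²⟩ over frames. When superposition is on
(the default), frames are least-squares fitted (Kabsch) onto the mean
structure of the selected atoms, the mean recomputed, and the fit iterated
up to 10 times or until the mean moves < 10⁻⁶ nm — the standard
mean-structure convention, which makes the estimate invariant (to 10⁻⁶ nm)
under arbitrary per-frame rigid transforms of the input. The identical
estimator applied to the models of a multi-model ensemble gives the
per-residue ensemble spread, so simulation RMSF and, say, an NMR ensemble's
RMSD overlay on the same scale by construction.

Superposition necessarily absorbs the six rigid-body degrees of freedom of
each frame, deflating the summed squared fluctuation by about 6σ²; with n
fitted atoms this is a relative bias of order 2/n on the mean-square
fluctuation, negligible for realistic selections (n ≳ 60) but visible in
synthetic closed-form checks — see the jitter generator below.

## Orientation landscape

Each frame's alignment selection is Kabsch-superposed onto a common
reference (a supplied structure, or frame 0 of replicate 0 by default). The
Kabsch solution is the weighted SVD construction with the reflection branch
corrected to det = +1; near-collinear point sets (second singular value
< 10⁻⁹ of the first) are rejected as underdetermined. The **pose** of a
frame is the rotation carrying the reference into the frame (the inverse of
the frame→reference alignment), so (θ, ψ) read as "how the body is oriented
relative to the reference".

The rotation is decomposed in the Tait–Bryan Z–Y–X convention,
R = Rz(φ)·Ry(θ)·Rx(ψ), the unique order under which θ = −asin(R₃₁) and
ψ = atan2(R₃₂/cos θ, R₃₃/cos θ); φ — rotation about the membrane normal —
is discarded as functionally irrelevant. asin confines θ to [−90°, 90°];
the mirrored branch θ′ = 180° − θ maps the same rotations, so one branch
already yields a complete landscape. Within `gimbal_tol` (10⁻⁶) of
cos θ = 0, ψ and φ are inseparable: the pose is flagged, ψ set to 0, and the
frame excluded from the density (with a logged count) while remaining in the
pose table.

The density is a Gaussian KDE (Scott's rule by default, factor exposed) over
the pooled non-gimbal (θ, ψ) pairs, evaluated on a 181 × 361 grid at 1°
spacing and renormalised so cell-area-weighted density sums to 1. If the
poses have (near-)zero variance the KDE is degenerate and all mass is placed
in the nearest cell. Modes are 8-neighbour local maxima ≥ 10% of the global
maximum (plateaus collapsed to their lexicographically first cell, ties
broken by lower (θ, ψ)); maxima closer than `min_mode_separation_deg`
(default 5°) to a denser one are suppressed, because twin peaks within a
kernel bandwidth are sampling noise rather than distinct poses. Every
non-gimbal pose is assigned to its nearest mode under the wrapped metric
√(Δθ² + Δψ²_wrapped) (ψ on (−180°, 180°]); the same metric drives
nearest-frame retrieval.

## Synthetic generators and what passing tests show

All generators are pure functions of their spec including the seed.

* **Pose mixtures** draw a component per frame, (θ, ψ) from independent
  clipped Gaussians around the component means, and φ uniform, then rotate a
  rigid pseudo-Cα body (≥ 4 non-coplanar points enforced) about its
  centroid. Independent clipped Gaussians rather than a proper rotational
  distribution (e.g. matrix-Fisher) keep the planted modes readable directly
  from the spec. The default demo condition uses two equal-weight components
  10° wide at (−30°, 40°) and (45°, −120°) over 2,000 frames — well
  separated relative to the KDE bandwidth, as mode-recovery claims require.
* **Contact kinetics** is a two-state Markov chain (unbound→bound w.p.
  p_on, bound→unbound w.p. p_off per frame) started in its stationary
  distribution so empirical occupancy is unbiased at any length; bound and
  unbound frames draw distances uniformly from ranges lying strictly below
  the lower and above the upper cutoff, making booking exact by
  construction. Closed forms: occupancy = p_on/(p_on+p_off), mean dwell =
  1/p_off (geometric). p_on or p_off of exactly 0 or 1 is permitted for
  degenerate fixtures (never/always bound). The standard validation
  condition is p_on = 0.05, p_off = 0.10 over 50,000 frames.
* **H-bond triplets** are realised exactly: donor at the origin, hydrogen
  1.0 Å along x, acceptor placed from the law-of-cosines solution
  r = h·cos α + √(d² − h² sin² α); unrealisable (d, α) combinations raise.
  Triplets are spaced 5 nm apart so they cannot cross-talk.
* **Jitter** adds per-residue isotropic Gaussian noise of stdev σ per axis
  and no rigid drift, so RMSF = √3·σ exactly. The fluctuation fixtures place
  the pseudo-Cα atoms on a spherical shell ("shell" arrangement, 200
  residues × 10,000 frames in the standard validation): on a shell the
  ~6-DOF superposition bias spreads evenly (≈ 2/n relative on the
  mean-square), keeping every residue within the 2% band; on a Gaussian blob
  it concentrates on peripheral atoms.

None of this emulates real membrane physics — no anchor tether dynamics,
no lipid diffusion, no correlated internal motion, no force field. Passing
tests therefore demonstrate that the *estimators* are correct (booking,
averaging, superposition, decomposition, density estimation), not that any
particular biological system behaves a given way. Distribution-level results
from real µs-scale simulations (tilt-angle ranges, linker-angle modes) are
not reproducible at fixture scale and are out of scope of the validation
suite; fixture sizes above were chosen as the smallest at which sampling
error sits comfortably inside each closed-form tolerance.

## Degenerate inputs and tie-breaks

Zero vectors in tilt, single-frame RMSF, empty selections, non-finite
distances, mismatched point sets, non-orthonormal rotation inputs, coplanar
reference bodies and overlap between fixture distance ranges and the cutoff
band all raise typed errors (`gpitraj.errors`). Selection results are always
sorted by atom index; multiple values in one selection clause OR together;
`not` binds tighter than `and`, which binds tighter than `or`. Mode ties are
broken lexicographically; ψ = −180° is folded to +180°.

## Limitations

* Only multi-model PDB trajectories are read natively; other formats must be
  adapted to the `(Topology, Trajectory)` contract by the caller.
* Residence times of events truncated by the trajectory end are biased low;
  no survival-censoring correction is applied.
* Donor/acceptor typing is name-table based and covers standard protein
  residues, phosphatidylcholines and cholesterol; other lipids need table
  extensions.
* The landscape KDE is Euclidean in (θ, ψ): it does not wrap across
  ψ = ±180° and ignores the sin θ measure of rotation space, which is
  adequate for well-separated clusters away from the poles but will distort
  densities near |θ| → 90°.
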