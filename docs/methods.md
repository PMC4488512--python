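# Methods

## The curve model

A helix is modelled as the one-parameter curve

    point(u) = r0 + R · ( r sin(u·t),  r cos(u·t),  u·p )

with radius `r > 0` (Å), per-residue rise `p ≥ 0` (Å; note this is the rise
per *residue*, not the crystallographic pitch per turn), per-residue turn
angle `t ∈ (0°, 360°)`, origin `r0` and proper rotation `R`; the helix axis
is `R·(0,0,1)`.  Consecutive integer values of `u` are one residue apart, so
the chord between neighbouring residues obeys

    d² = p² + 4 r² sin²(t/2)                                   (chord identity)

which is inverted to compute `t = 2 arcsin(½ √(d² − p²) / r)` from a fitted
(r, p) pair and the observed Cα–Cα distance.  A left-handed curve negates
the angular argument; mirroring coordinates (x → −x) maps the right-handed
trace exactly onto the left-handed one with the same (r, p, t), which is how
left-handed helices are detected without a second curve model.

The model assumes constant radius, rise and turn along each four-residue
window — conical or super-helical (coiled-coil scale) curvature is absorbed
into the window-to-window axis angle rather than the per-window fit.

## Quadruple fitting

Per sliding window of four Cα atoms:

1. **Initial estimates.**  The two second-difference vectors of the trace
   are perpendicular to the axis for on-curve points; their cross product
   gives the axis direction (oriented along the chain so the rise is
   non-negative).  Projecting the four points onto the axis-normal plane
   gives points on a circle, recovered by a linear least-squares (Kåsa)
   fit; the radius is the mean distance of the projections to the centre,
   the turn angle the mean angular step, and the rise the mean axial bond
   projection.  Exact for ideal quadruples; collinear or coincident
   quadruples raise a degeneracy signal and the fit is marked invalid.
2. **Grid search.**  r and p are scanned exhaustively over ± 0.25 Å around
   the estimates in 0.01 Å steps (grid endpoints inclusive; both the
   half-widths and the step are configurable).  Per cell, `t` follows from
   the chord identity using the mean of the three consecutive Cα distances;
   cells with `d ≤ p` or an arcsine argument above 1 are skipped.  The
   candidate curve's four index points are superposed onto the quadruple by
   Kabsch/SVD (proper rotations only; the batched RMSD uses the
   singular-value identity).  The minimizing cell wins; ties break
   deterministically by scan order (ascending r, then p).
3. **Reported quantities.**  The superposition objective is the index-paired
   RMSD; the reported Δ is the closest-point RMSD of the four atoms to the
   winning curve, each distance found by bounded 1-D minimization over a
   ±1-residue parameter window (tolerance 1e-8) so the search cannot jump
   to the next turn.  Both values are exposed (`pair_rmsd`, `delta`); for
   well-fitting quadruples they agree closely.  The fitted axis is oriented
   with positive projection on the Cα_i → Cα_{i+3} displacement so that
   consecutive-axis angles are well defined.

Per residue `i` the profile carries the axis angle `a_i` (0.0 for the first
profiled residue of a segment, which has no predecessor axis), Δ_i, and the
seven-residue RMSD δ_i: the RMS pooled over all (curve, member-atom)
closest-point distances of the up-to-four valid quadruple curves starting
at i−2 … i+1.  Pooled RMS (rather than a per-curve average) was chosen
because it weighs every atom–curve pair equally and degrades gracefully
when only some covering quadruples exist; quantities with no defined value
are stored as `inf`, so every `< threshold` test on them fails —
window logic near segment ends needs no special-casing.

## Scores and the standard protein helices

Each class (α, 3₁₀, π) carries normal parameters (μ, σ) for r, p, t and Δ:

| class | μ_r   | σ_r   | μ_p   | σ_p   | μ_t   | σ_t  | μ_Δ   | σ_Δ   |
|-------|-------|-------|-------|-------|-------|------|-------|-------|
| α     | 2.314 | 0.061 | 1.516 | 0.086 | 100.1 | 2.56 | 0.020 | 0.031 |
| 3₁₀   | 2.109 | 0.118 | 1.829 | 0.138 | 107.4 | 5.90 | 0.045 | 0.038 |
| π     | 2.779 | 0.086 | 1.196 | 0.056 | 82.8  | 2.80 | 0.129 | 0.056 |

The (μ_r, μ_p, μ_t) triple of a class is its *standard protein helix*.  A
residue's score for a class combines the standardized squared deviations of
its fitted (r, p, t, Δ); the Δ term is Δ²/σ_Δ² (deviation from zero — μ_Δ is
stored but unused, since an ideal helix has Δ = 0).

**Combiner choice.**  This is the one genuinely open design point and the
default deviates deliberately from the most literal reading.  Three
combiners are implemented:

- `sum` (default): Σ (x − μ)²/σ², squared z-scores.
- `halfsum`: Σ (x − μ)²/2σ², the Gaussian-exponent terms summed.
- `product`: Π (x − μ)²/2σ², the score formula read literally as a product.

The product collapses to zero whenever a single parameter hits its class
mean, destroying inter-class discrimination entirely (an ideal α-helix would
score 0 for all three classes).  The halved sum fails more subtly: an exact
standard α-helix scores g = 4.85 against the 3₁₀ class, *below* the 3₁₀
start threshold g_T = 6 — and since the 3₁₀ pass precedes the α pass, every
good α-helix would be claimed as 3₁₀.  The un-halved z² sum is the only one
of the three that separates all classes at the stated thresholds (the same
α-helix then scores g = 9.7 > 6, while every class still scores 0 against
itself); it is therefore the default, with the other two available for
experimentation via `--combiner`.

## Assignment

Per chain segment and handedness, three sequential passes over a shared
per-residue assigned flag `b` (set once, never cleared except when a
sub-minimal run is discarded back to the unassigned pool):

1. **π:** start where π_i < π_T (14) and a_i, a_{i+1}, a_{i+2} < a_I (20°);
   grow while π_i < π_T; then take four trailing residues (clipped to the
   segment end and to unassigned residues); discard runs shorter than 5.
2. **3₁₀:** start where g_i < g_T (6) and a_i < a_G (10°); grow while
   g_i < g_T; extend the C-terminus by two residues if δ_i < δ_G (0.12 Å)
   at both; discard runs shorter than 3.
3. **α:** start where h_i < h_T (20), a_i < a_T (20°) and h_{i+1} < h_T;
   grow while h_i < h_T.  Adjacent α runs fewer than four residues apart
   merge when every intermediate residue has a ≤ a_max (40°), h < h_max
   (160) and δ < δ_max (0.3 Å); merging cascades left-to-right.  Each run's
   C-terminus is then extended by two residues when the first residue past
   it is unassigned with h < h_max and a < a_max.  Final runs shorter than
   4 are discarded.  Merging and extension apply to α only.

The left-handed pass runs after all right-handed passes, on mirrored
coordinates with identical thresholds and class parameters, claiming only
still-unassigned residues.  Output is deterministic: identical coordinates
and configuration give byte-identical output.

Boundary semantics near segment ends follow one rule: score/angle/RMSD
values that do not exist (the last three residues of a segment have no
quadruple; invalid fits have no parameters) are `inf` and fail every
threshold test, and all fixed-count extensions clip to the segment end and
to unassigned residues.

## Input handling

PDB files are read through gemmi (first model only).  One Cα per residue is
retained; alternate locations resolve by highest occupancy, ties by lowest
altloc letter.  HETATM Cα atoms of common modified amino acids (MSE, SEC,
…) are kept; waters, ligands and calcium ions are not.  Chains split into
segments wherever a consecutive Cα–Cα distance leaves the [2.5, 4.3] Å
window — wide enough for trans (~3.8 Å) and cis (~2.9 Å) peptide bonds —
and each segment is assigned independently; residue-numbering gaps alone do
not split.  Structures with disordered (missing) Cα atoms therefore get
their helices assigned per contiguous fragment.

## Synthetic data

The fixture generator emulates the geometric content of real traces, not
their chemistry:

- **single**: points exactly on a chosen curve, optionally with isotropic
  Gaussian coordinate noise (seeded, reproducible).  Realistic crystal
  coordinate uncertainty corresponds to σ ≈ 0.05–0.15 Å.
- **helix-in-coil**: a planted helix with extended-strand flanks
  (r = 0.96 Å, p = 3.34 Å, t = 177.9°, the mean β/extended geometry)
  attached collinearly at 3.8 Å.  Strand quadruples score two to three
  orders of magnitude above every helix threshold, so the flanks can never
  be helix-called; junction-spanning quadruples fit poorly (large Δ) or are
  degenerate.  Planted lengths in tests (α 12, 3₁₀ 7, π 8) are chosen so
  each class has at least two consecutive interior window starts — the
  first in-helix window's axis angle references a junction-spanning fit and
  may legitimately fail its gate, shifting the detected start by one.
- **kinked**: two ideal helices joined with a prescribed inter-axis angle,
  for bend/merge behaviour.
- **mirrored**: the x-inverted trace, a genuine left-handed helix.

What passing on these fixtures does *not* show: real loops are far more
varied than ideal strands, real helices bend and fray, and crystallographic
noise is anisotropic and correlated.  The fixtures validate the algorithm's
logic and numerics, not its agreement rates with hydrogen-bond assigners on
the PDB.

## Calibration and clustering

`fit_normal` (moment fit, population-σ denominator — a fixed documented
convention), `pi_average` (the component-wise mean of the first three
residues' (r, p, t), the convention under which π-helix statistics are
collected) and `cluster_helices` support re-deriving class parameters from
labelled data and comparing assigned helices structurally.  Clustering is a
greedy leader pass in input order under a Kabsch-RMSD threshold (default
1.5 Å) over equal-length Cα sets: deterministic, order-dependent, and a
partition by construction.  It is a simple stand-in for more elaborate
geometric clustering; cluster *counts* on large collections should not be
over-interpreted.

## Numerical choices

- Kabsch superposition excludes reflections (det +1 enforced); degenerate
  (collinear/coincident) point sets raise rather than silently reflect.
- The grid search evaluates all cells with one batched 3×3 SVD; the winning
  cell's transform is recomputed explicitly.
- Closest-point searches use scipy's bounded scalar minimizer at 1e-8
  parameter tolerance within ±1 residue.
- Acceptance-scale problem sizes: 30-residue traces, one interior quadruple
  per class; fixture tests use 7–20-residue segments.  The whole suite runs
  in well under a minute on one CPU.

## Known limitations

- Windows of exactly four residues: helices are characterized locally; a
  global best-fit helix per assigned run is not recomputed (the test suite
  checks one-curve refits post hoc).
- Thresholds and class parameters are taken as given; re-deriving them
  requires externally labelled structures and is out of scope here beyond
  the generic `fit_normal`/`pi_average` helpers.
- β-structure, turns and polyproline are out of scope; unassigned simply
  means "not helical by these criteria".
- mmCIF input is not implemented; PDB format is the supported dialect.
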