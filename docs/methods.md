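# Methods

## Model

A folded structural unit is idealized as a fuzzy micelle: its hydrophobicity
density is a 3D Gaussian spanning the unit.  The unit is centered on the
centroid of its effective atoms and rotated into its principal frame
(descending extent; axis signs fixed so the farthest residue along each of
the first two axes has a positive coordinate, the third axis sign preserving
handedness — output is deterministic).  The Gaussian widths follow the 3σ
rule, σ_axis = max|coordinate|/3, so the molecular boundary sits at three
standard deviations (~99.7% of the Gaussian mass inside the molecule).  An
alternative `range_6` convention ((max−min)/6 per axis) is available for
sensitivity checks; both are recorded in run manifests.

The theoretical profile T samples this Gaussian at the effective atoms and
normalizes to unit sum.  The observed profile O sums pairwise interactions
(H_i + H_j)·w(r_ij) over residue pairs within a cutoff, including the self
term (r = 0, w = 1), where w is Levitt's contact polynomial
1 − ½(7x² − 9x⁴ + 5x⁶ − x⁸), x = r/c, zero beyond the cutoff.  The self
term makes single-residue fragments well defined.  The uniform reference R
is 1/N.

Divergences are Kullback–Leibler entropies reported in bits; the relative
distance RD = D(O|T)/(D(O|T)+D(O|R)) and the optimal K are both invariant
to the logarithm base (the base cancels in the ratio and under the monotone
transform of the objective), which the test suite verifies.  The modified
field is M(K) = [T + K·(T_MAX − T)_n]_n: K scales the *normalized* opposite
field before final renormalization.  The stepwise construction (normalize
the opposite term, mix, renormalize) makes M(0) = T exact and M(K→∞) the
opposite field.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| hydrophobicity scale | `fauchere_pliska` | dimensionless, min–max to [0,1] | experimental octanol/water partition scale widely used for residue hydrophobicity; `kyte_doolittle` and `eisenberg` ship as alternatives. The scale is a mandatory, logged config item because results depend on it up to an affine rescaling of the raw table. |
| Levitt cutoff c | 9.0 | Å | standard residue-contact range for the Levitt function. |
| σ convention | `max_extent_3` | — | 3σ rule; see above. |
| K search | [0, 10], step 0.01 | — | grid scan followed by bounded local refinement (xatol 1e-6). K is reported at 2 decimals. The domain comfortably contains chaperonin-regime values (K ≈ 4–7); an inverted-micelle O can pin K at the upper bound, which is reported as-is. |
| elimination threshold | RD < 0.5 | — | the hydrophobic-core criterion. Elimination is iterative-greedy: remove the residue with max |O_i − T_i| (ties → lower sequence position), renormalize, recompute; stops with a non-convergence report rather than an exception if fewer than 3 residues would remain. |
| excess/deficit tolerance | 1/(4N) | profile units | a quarter of the uniform level; scale-free, so segment calls are comparable across unit sizes. |
| layer thresholds | 0.001 / 0.0015 | normalized profile units | absolute levels on complex-normalized profiles separating surface (both low), subsurface-conforming (both high) and core-deficit (T high, O low) residues. |
| contact cutoff | 5.0 | Å | any-heavy-atom-pair distance, the common protein–protein interface convention; an effective-atom basis is available and is always a subset at equal cutoff. |

## Structure handling

Effective atoms average heavy atoms only (deposited crystal structures
rarely carry hydrogens; excluding them keeps results model-independent).
Waters and non-amino-acid heteroatoms never enter profiles.  Multi-model
files use the first model; altlocs resolve to the highest-occupancy
conformer with ties to file order.  Missing residues are simply absent —
profiles index over the residues present, with no imputation.  When the
Gaussian scope is a complex, orientation and σ come from the complex point
cloud, profiles are computed (and normalized) over the complex, and a
fragment's status is obtained by extracting its T_i/O_i, renormalizing each
to unit sum, rebuilding R at the fragment length and recomputing RD and K —
so `fragment_status(whole) ≡ unit_status(whole)`.

## Synthetic regimes

The fixture generator emulates the two folding-environment extremes and
three probes:

- *ideal micelle*: residues uniform in a ball of radius 15 Å; each position
  is assigned the standard amino acid whose scale value is nearest the local
  Gaussian density, so O tracks T by construction.  Across seeds 1–10 at
  n = 200 this yields RD < 0.3 and K ≤ 0.2.
- *inverted micelle*: the same geometry with the assignment reversed
  (hydrophobic outside): RD > 0.5 and K ≥ 1.0.
- *uniform blob*: one residue type; O is near uniform, RD near 1.
- *perturbed micelle*: ideal micelle plus a spatially coherent surface patch
  (the outermost residue and its n/12 nearest neighbours, contracted toward
  the anchor and forced maximally hydrophobic, reordered to be
  sequence-contiguous).  The contraction concentrates Levitt contacts so the
  patch dominates the |O − T| ranking and greedy elimination removes a patch
  residue first.
- *engineered dimer*: two ideal micelles 120 Å apart with one hydrophobic
  contact pair 4 Å apart at the midpoint.

What the fixtures do **not** emulate: peptide-bond geometry, side-chain
packing, secondary structure, chain connectivity in space, crystallographic
artifacts (altlocs, partial occupancy beyond the parser tests), or realistic
interface areas.  Passing the regime suite shows the statistics respond to
hydrophobicity architecture as intended; it does not validate predictions on
real deposited structures, which additionally depend on the hydrophobicity
scale and σ convention chosen.

## Numerical choices and degenerate inputs

- Zero-term convention 0·log(0/q) = 0; T is strictly positive by
  construction so support errors can only arise from user-supplied profiles.
- The degenerate RD denominator (O = T = R) returns RD = 0 with an explicit
  flag, never silently.
- A constant T makes the opposite field (and hence M and K) undefined and
  raises a profile error; an all-zero hydrophobicity scale is rejected at
  scale construction and again when O sums to zero.
- Units with fewer than 3 residues or collinear geometry cannot be oriented
  and raise a geometry error; fragment extraction from complex profiles has
  no such limit (a one-residue interface is valid and reports the degenerate
  status).
- The K refinement never returns a value worse than the best grid point, so
  D_KL(O|M(K*)) ≤ D_KL(O|T) holds exactly (K = 0 is on the grid).

## Open design points

- The intrinsic hydrophobicity scale is deliberately configurable and
  mandatory-logged: published RD/K values for real chaperonin complexes are
  sensitive to it, and reproducing them may require the exact (unpublished
  here) scale; the package's defaults are chosen as the field's common
  conventions, not fitted to any target values.
- K is applied to the normalized opposite term before final renormalization
  (the reading consistent with M(0) = T and the stepwise construction).
- Elimination is greedy-with-recomputation; a one-shot ranked variant was
  considered and rejected as the default because recomputation changes the
  ranking after each removal.
- Problem sizes in the test and acceptance runs (n = 200 residues, seeds
  1–10) were chosen to make the regime statistics stable while keeping the
  full suite fast.

## Limitations

- Residue-level only: no all-atom hydrophobicity field, no hydrogens, no
  structure repair or biological-assembly expansion.
- The published-value reproduction check requires the deposited coordinate
  files locally (they are too large to ship); without them it reports
  failure rather than silently passing.
- Interface residue lists from the literature are not treated as ground
  truth (contact criteria differ between tools); only the package's own
  stated criterion is tested.
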