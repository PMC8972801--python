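# Methods

This note records the models, conventions and numerical choices behind
`pyranoid`, and what its synthetic benchmarks do and do not demonstrate.

## Cremer–Pople conventions

The forward transform follows the standard prescription for a
six-membered ring: centre the ring at its geometric mean, define the
mean plane by requiring the two first-order trigonometric moment sums of
the out-of-plane displacements to vanish (the plane normal is
**R**′ × **R**″ with **R**′ = Σ **r**ⱼ sin(2πj/6),
**R**″ = Σ **r**ⱼ cos(2πj/6)), then read (q₂, φ₂) off the second-order
Fourier sums and q₃ off the alternating sum.  Two conventions are fixed
once and used everywhere:

- **Indexing**: j = 0 is the ring oxygen and the traversal runs towards
  the anomeric carbon.  With this choice θ = 0 is the
  ⁴C₁ chair of a D-aldopyranose and θ = 180° is ¹C₄.
- **Handedness**: the positive Cremer–Pople side of the ring is the side
  from which the numbering appears clockwise.  The inverse transform
  (`build_ring`) therefore places its hexagon clockwise when viewed from
  +z; this also makes the O5–C1–C2–C3 torsion of a ⁴C₁ chair positive
  (+54.3° at Q = 0.55 Å, radius 1.45 Å), matching the sign of the values
  stored in released dictionary entries.

Because the Cremer–Pople displacement harmonics are orthogonal to the
mean-plane conditions on a regular hexagon, the forward∘inverse round
trip is exact to machine precision (the test grid asserts 1e-6).

The φ origin (and hence which skew-boat is called ¹S₅ versus ⁵S₁)
differs between published implementations.  Here the canonical table is
*derived* rather than transcribed: each boat/skew/envelope/half-chair is
generated by projecting its defining displacement pattern (which atoms
sit above/below the reference plane) through the forward transform, so
names and (θ, φ) positions are mutually consistent by construction.
This puts the boats at φ = 0°, 60°, …, skew-boats at 30°, 90°, …, and
O,3-boat ("O3B") at φ = 0.

Conformer labels are positional: locants O, 1…5 name ring positions
starting at the oxygen, position 1 being the anomeric carbon.  For
aldopyranoses these are the chemical locants; for ketopyranoses (ring
O6–C2…C6) the chemical 2C5 chair of sialic acid becomes the positional
label "1C4", which is also how such sugars are conventionally depicted.

Envelopes and half-chairs are both tabulated on the tropics
(θ = 54.74°/125.26°).  The ideal-projection latitude of a half-chair is
actually 50.8°/129.2°; the ~4° difference never changes a
nearest-neighbour assignment and keeps the table on two clean
latitudes.  Classification is nearest canonical point by spherical arc
distance, ties broken chair → boat/skew → envelope/half-chair, then
lexicographically.  Rings with Q < 0.1 Å are reported as planar with
θ, φ undefined (0.1 Å is well below any physical pucker, which sits
near 0.55–0.63 Å for chairs).

## Patching

The six endocyclic torsions are measured from the dictionary's own
conformer and written as `ring_1`…`ring_6` with period 1 (the
monomer-library encoding of a unimodal restraint) and σ = 3.0°;
numbering starts at the quadruple that runs ring-oxygen → anomeric
carbon, so `ring_1` is O5–C1–C2–C3 for an aldopyranose.  The σ = 3.0°
default holds the ring firmly (a whole-ring flip costs hundreds of
σ-units) while leaving thermal-scale wiggle; alternative settings such
as 6.0° or 10.0° are reproducible through the `--sigma-ring` knob, and
the regularizer benchmark below shows how the grip weakens as σ grows.
All
other torsions are renamed `tors_k`, re-measured from the conformer when
their atoms are present, and kept at σ = 10.0° (tighter input sigmas are
preserved).  Torsions involving hydrogens are dropped by default
(`include_hydrogens=False`): riding hydrogens carry no independent
conformational information.  Patching never touches bonds, angles,
chiralities, planes or the component type, and is idempotent.

Numeric fields are written with three decimals, which both reproduces
printed two-decimal dictionary values exactly and makes
write → read → write byte-identical.

## Validation criteria

- **Anomeric configuration**: the sign of the anomeric substituent's
  bond vector against the traversal-oriented ring normal.  This sign is
  a stereodescriptor (α-D and β-L negative, β-D and α-L positive, with a
  per-component override for ketoses), not an axial/equatorial
  threshold, so it is stable under ring deformation — a boat-only
  distortion is *not* reported as a wrong anomer.  A missing substituent
  (glycosidic linkage) is indeterminate and passes with a warning.
- **Chirality**: sign of the scalar triple product of the three
  centre→neighbour vectors against the dictionary's volume sign.
- **Amplitude**: Q within [0.35, 0.9] Å (configurable); brackets
  physically sensible six-ring puckers around the chair band.
- **Conformation**: the classified label must equal the expected
  low-energy conformer (D-series saturated → 4C1, L → 1C4, per-component
  overrides, e.g. SIA → positional 1C4).  Label equality rather than a
  θ window is used so that envelope/half-chair drift is flagged.

Verdict: **yes** iff all four pass; **check** iff conformation is the
sole failure; otherwise **no**.

The shipped expectation table covers NAG, MAN, BMA, GLC, BGC, BOG, FUL,
GAL, GLA and SIA; anything else defaults to a D-series chair and can be
overridden with a user TSV.

## Synthetic data

`make_sugar` builds rings by the inverse Cremer–Pople transform
(Q = 0.55 Å, hexagon radius 1.45 Å) and places substituents with ideal
tetrahedral geometry (C–C 1.52 Å, C–O 1.43 Å, C–N 1.47 Å) in a
gluco-like all-equatorial pattern, the anomeric substituent axial
(alpha) or equatorial (beta); L-sugars are exact mirror images of the D
build.  The generated dictionary mimics a generator's pre-patch state:
measured bond/angle targets (σ 0.02 Å / 2.0°), chirality signs computed
from the built coordinates, torsion targets rounded to the nearest 60°
with σ = 10°, period 3.  The legacy variant collapses all torsions to a
uniform σ = 20° with heuristic periodicities (C–C central bond → 3,
O → 6, N → 2), reproducing the old-style entries that predate the
ring/other separation.

What this emulates: the logical structure of real entries — correct
connectivity, stereochemistry, conformer coordinates, restraint loops.
What it does not: database-mined bond/angle target values, hydrogen
atoms, acetyl/glycerol side-chain detail, crystallographic density.
Tests passing on these fixtures demonstrate the geometry, patching and
diagnosis logic, not agreement with any particular released dictionary's
numeric targets.

`distort_ring` interpolates the pucker linearly in the Cartesian pucker
space (q₂cosφ, q₂sinφ, q₃), rigidly re-aligns the rebuilt ring and
carries each substituent in the local frame of its anchor ring atom,
preserving chirality along the whole path.

The reference GlcNAc conformer used for the stored-torsion benchmark is
regenerated with RDKit (ETKDG embeddings, MMFF94 minimization, lowest
energy kept).  The resulting O5–C1–C2–C3 torsion lands in near-degenerate
rotamer basins spanning roughly 49–57° depending on the embedding seed,
around the 53.65° stored in the released entry; the released value also
reflects a final idealization against database-mined targets that this
regeneration intentionally omits.

## Toy regularizer

The energy is Σ((measured − target)/σ)² over bond, angle and torsion
restraints, minus weight × Σ ρ(xᵢ) for an optional trilinearly
interpolated density term; gradients are analytic (verified against
central differences at 1e-5) and minimization is L-BFGS-B with an
energy tolerance of 1e-8.  Torsion residuals are wrapped to
(−180°, 180°] and honour the restraint period (nearest of the p
symmetry-equivalent targets), which is exactly why only period-1
restraints single out one ring conformation.

This is not a crystallographic refinement engine: no structure factors,
B factors, solvent or bulk-weighting.  It exists to make three
behaviours observable at desk scale, each asserted by the test suite on
an ensemble of 50 boat-distorted, jittered starts (seed 4117):

1. with σ = 3° ring torsions ≥ 95% of starts return to within 10° of
   the chair pole;
2. with bonds and angles only, ≤ 10% do (the boat satisfies them);
3. with a sharp, strongly weighted density term shaped like the boat
   (Gaussian width 0.3 Å, weight 2000 — the "strong data" regime), the
   boat is retained (final θ > 60°).

The density stand-in for RSCC is a sum of unit-height isotropic
Gaussians (width 0.9 Å, mask radius 2.5 Å around the sugar, both
configurable).  RSCC values are therefore comparable only within this
package; the qualitative property that matters — density generated from
one conformer correlates better with that conformer's model than with
the other's — is what the tests assert.

## Known limitations

- Single-residue monomers only; no fused/bridged polycyclics (no SSSR),
  no furanoses (five-membered pseudorotation is a different formalism).
- The anomeric check needs the anomeric substituent present; fully
  substituted glycosides validate as indeterminate on that criterion.
- Expectation defaults treat all ten shipped components as saturated
  chairs; unsaturated sugars need an explicit expected conformer.
- The problem sizes used in tests and the acceptance script (single
  monomers, ~12-atom fixtures, 50-start ensembles, 20 conformer
  embeddings) were chosen to exercise every code path at desk scale.
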