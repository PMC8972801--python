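# pyranoid

Conformation-aware restraint dictionaries and model validation for
pyranose sugars.

## The problem

Carbohydrates are usually the worst-modelled parts of macromolecular
structures: they are flexible, often poorly resolved, and sit at the
edges of the density.  A pyranose (a six-membered sugar ring of five
carbons and one oxygen) strongly prefers a single chair conformation —
<sup>4</sup>C<sub>1</sub> for D-sugars, <sup>1</sup>C<sub>4</sub> for
L-sugars — yet refinement guided only by bond and angle restraints will
happily let a ring sink into noisy density as a boat or skew-boat,
because those distortions cost almost nothing in bond/angle terms.

The remedy implemented here is a *torsional* one: measure the six
endocyclic torsion angles from a low-energy reference conformer and
write them into the monomer-library restraint dictionary as **unimodal**
restraints (`ring_1`…`ring_6`, period 1, σ = 3.0°), kept separate from
the remaining torsions (`tors_*`, σ = 10.0°) so refinement programs can
activate them independently.  A generic 60° target is wrong for a
pyranose — the endocyclic oxygen makes the ring bonds unequal, so e.g.
the O5–C1–C2–C3 torsion of *N*-acetyl-β-D-glucosamine is 53.65°, not
60°.  The package is aimed at people who build or validate
carbohydrate models and at developers of restraint-generation and
validation pipelines.

## What is inside

- **Cremer–Pople analysis** (`pyranoid.puckering`).  For ring positions
  **R**<sub>j</sub> (j = 0 at the ring oxygen, traversal towards the
  anomeric carbon), displacements z<sub>j</sub> from the unique mean
  plane give the puckering coordinates

  q₂ cos φ₂ = √(2/6) Σ z_j cos(4πj/6), q₂ sin φ₂ = −√(2/6) Σ z_j sin(4πj/6),
  q₃ = 6^(−1/2) Σ (−1)^j z_j,
  Q = (q₂² + q₃²)^(1/2), θ = atan2(q₂, q₃), φ = φ₂,

  plus the exact inverse transform (place any conformer at any
  amplitude) and nearest-neighbour classification against the 38
  canonical conformers (2 chairs, 6 boats, 6 skew-boats, 12 envelopes,
  12 half-chairs).
- **Ring detection and metric geometry** (`pyranoid.ring_geometry`):
  connectivity-based pyranose detection (works for ketopyranoses and
  non-standard atom names), IUPAC-convention dihedrals, ring torsions.
- **Dictionary I/O and patching** (`pyranoid.cif_io`,
  `pyranoid.torsion_patcher`): read/write monomer-library CIF entries
  (round-trip exact), patch them with measured ring torsions, diff old
  versus new entries.
- **Validation** (`pyranoid.validation`): per-sugar diagnosis of
  anomeric configuration, chirality, puckering amplitude and ring
  conformation into the verdict **yes** (all pass) / **check** (only the
  conformation is unexpected — inspect the density) / **no** (anything
  else wrong).
- **Density and RSCC** (`pyranoid.density_rscc`): synthetic Gaussian
  model density and the masked real-space correlation coefficient.
- **Toy restrained regularizer** (`pyranoid.restrained_min`): a
  quadratic restraint energy with analytic gradients that makes the
  refinement behaviour of the new restraints observable at desk scale.
- **Synthetic fixtures** (`pyranoid.synthetic_fixtures`): idealized
  sugars at any conformer, generator-style and legacy-style
  dictionaries, ring distortion with stereochemistry preserved.

## Worked example

```sh
$ pyranoid fixtures make-sugar --comp-id NAG --out-pdb NAG.pdb --out-cif NAG.cif
wrote NAG.pdb and NAG.cif
$ pyranoid patch --dict NAG.cif --coords NAG.pdb --out NAG_patched.cif
NAG: 6 ring torsions (sigma 3.0), 3 other (sigma <= 10.0) -> NAG_patched.cif
```

The patched torsion loop now separates the unimodal ring torsions from
the rest (values in degrees, measured from the conformer, not generic):

```
NAG ring_1 O5 C1 C2 C3 54.340 3.000 1
NAG ring_2 C1 C2 C3 C4 -54.348 3.000 1
...
NAG tors_1 O1 C1 C2 C3 174.575 10.000 3
```

Distort the ring into a skew-boat and validate it:

```sh
$ pyranoid fixtures distort --coords NAG.pdb --dict NAG.cif --theta 90 --phi 270 --out-pdb NAG_boat.pdb
$ pyranoid validate --model NAG_boat.pdb --dict-dir dicts/ --out report.tsv
verdict count
yes     0
check   1
no      0
```

The per-sugar row shows why: `Q 0.552, theta 90.0, conformer 1S5,
verdict check, failed conformation` — the stereochemistry is intact, so
only the high-energy ring pucker needs checking against density.
Finally, regularizing the boat under the patched dictionary pulls it
back to the chair:

```sh
$ pyranoid demo-refine --dict NAG_patched.cif --start boat --out-pdb refined.pdb
final energy 0.0009988, theta 0.0 deg, converged=True -> refined.pdb
```

Starting θ was 90° (boat); the unimodal ring torsions take it to θ = 0°
(the <sup>4</sup>C<sub>1</sub> chair).  Running with
`--no-ring-torsions` instead leaves the ring in the boat, and adding a
strong boat-shaped density term (`--density boat.mrc --weight 2000`)
holds the boat against the torsions — the same trade-off a refinement
program exhibits when strong data down-weight the geometry term.

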