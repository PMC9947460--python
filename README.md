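# sansfem

An axisymmetric finite-element model of the human eye and orbit under
orbital-fat swelling — the biomechanical mechanism proposed for
spaceflight-associated neuro-ocular syndrome (SANS).  In microgravity the
cephalad fluid shift raises the water content of the retrobulbar fat; the
swelling fat loads the globe and produces the ocular signs seen in
astronauts: globe flattening, axial shortening, choroidal folds, and (the
model predicts) subtle proptosis.

The package is aimed at ocular-biomechanics researchers who want a fully
scriptable, dependency-light re-implementation of this model: parametric
anatomy, neo-Hookean tissues with hygroscopic swelling, a staged loading
protocol, and drivers for the sensitivity studies.

## Model in brief

All tissues are incompressible neo-Hookean (`mu = E/3`); water uptake is a
multiplicative swelling `F = F_e J_H^{1/3} I` with
`eps_H = beta (C_W − C_W0)` and `J_H = (1 + eps_H)^3`.  Four loads act on
the globe: the IOP (generated by vitreous swelling in a volume-constrained
chamber), an ICP traction on the subarachnoid annulus of the peripapillary
sclera, the lumped rectus-muscle tension
`F_EOM = 4M(−0.29 w + 4.79 e^{w/4.57} − 3.01)` mN at the insertion ring,
and the frictionless contact force of the swelling fat.  The axial balance
`F_ICP + F_fat − F_EOM − F_ON = 0` holds to <0.1% at every converged state
(the optic nerve stays slack throughout).

Each simulation runs a four-stage protocol: (A) identify the zero-stress
eye by a coordinate search, (B) load it to the residually stressed,
pressurized eye, (C) seat it in the orbit while ramping muscle tension and
ICP to the terrestrial state, and (D) increment fat swelling (schedule
`eps_H = 0 … 0.07`) to the microgravity states.  Outputs — proptosis,
axial-length change, peripapillary arc-length change (posterior quarter of
the inner sclera), and posterior radius of curvature (Pratt circle fit
within 4 mm of the axis) — are reported for stage D relative to stage C.

There is no FEM dependency: the axisymmetric large-deformation kernel
(arbitrary-order Lagrange quads, augmented-Lagrangian incompressibility and
frictionless slip ties, energy-line-search Newton) lives in
`sansfem.fem`.  See `docs/methods.md` for the full model description,
the geometry reconstruction choices, and known limitations.

## Worked example

```python
from sansfem.loads import LoadCase
from sansfem.protocol import run_protocol

res = run_protocol("baseline", load_case=LoadCase(eps_H_fat=[0.0, 0.01, 0.07]))
print(res.table()[["eps_H_fat", "J_H_fat", "proptosis_mm",
                   "delta_axial_length_um", "delta_arc_um",
                   "delta_roc_mm", "F_EOM_mN", "F_fat_mN"]].round(3))
```

prints (coarse mesh, order 2):

```
   eps_H_fat  J_H_fat  proptosis_mm  delta_axial_length_um  delta_arc_um  delta_roc_mm  F_EOM_mN  F_fat_mN
0       0.00    1.000         0.000                  0.000         0.000         0.000     7.054     5.904
1       0.01    1.030         0.521                  2.339        -0.151         0.010     8.753     7.603
2       0.07    1.225         3.818                 12.775        -1.278         0.078    27.519    26.368
```

Reading: a 1% added-water fraction in the fat (3% volume increase) pushes
the eye 0.52 mm forward; at 7% water (22.5% volume) proptosis reaches
3.8 mm, the muscle tension needed to hold the eye has risen from 7.1 to
27.5 mN, the posterior pole has flattened (radius of curvature +0.08 mm)
and the peripapillary sclera has lost ~1.2 um of arc length — the fold-risk
proxy.  The axial-length column is the one output whose published sign
(shortening) this reconstruction does not reproduce; `docs/methods.md`
discusses why.

Command-line drivers mirror the study's analyses:

```bash
sansfem table2   --out out/            # baseline swelling table
sansfem icp-grid --icp 0 10 20 --eps 0 0.035 0.07 --out out/
sansfem anatomy  --out out/            # +10% single-dimension perturbations
sansfem stiffness --e-sclera 0.25 0.5 1.5 5 --out out/
sansfem mesh-check --out out/          # mesh quality + VTK/MSH export
```

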