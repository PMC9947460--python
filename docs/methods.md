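# Methods

`sansfem` is an axisymmetric finite-element model of the human eye and orbit
under orbital-fat swelling, built to study the biomechanics proposed to
underlie spaceflight-associated neuro-ocular syndrome (SANS): a cephalad
fluid shift raises the water content of the retrobulbar fat, the swelling
fat loads the globe, and the globe responds with proptosis, axial
shortening, posterior flattening and loss of peripapillary choroidal
tension.

## Model

### Tissues

All soft tissues are incompressible, isotropic neo-Hookean solids with
shear modulus `mu = E/3`:

| tissue        | E            | role in the solve                        |
|---------------|--------------|------------------------------------------|
| ocular coats  | 1.5 MPa      | meshed shell (sclera + cornea lumped)     |
| vitreous      | 6.5 Pa       | fluid cavity (uniform-pressure chamber)   |
| orbital fat   | 700 Pa       | meshed, hygroscopically swelling          |
| orbital bone  | rigid        | fixed displacement boundary               |
| dura / axons  | 1.5 MPa / 30 kPa | geometric only (the nerve stays slack) |

Water uptake enters through a multiplicative hygroscopic split
`F = F_e * J_H^(1/3) I` with `eps_H = beta (C_W - C_W0)`,
`J_H = (1 + eps_H)^3` and `beta = 1e-3 m^3/kg`; the added-water column of
the baseline schedule is read directly as the hygroscopic strain.

The vitreous is not meshed: because its shear modulus is ~10^5 times below
the sclera's, it acts as an incompressible pressure chamber.  The chamber
volume is constrained to `J_Hv * V0` with a water-like volumetric stiffness
(0.22 GPa); the chamber pressure is the IOP.  A direct prescribed-pressure
mode exists and agrees with the swelling mode to well under 1%.  A
consequence is that the vitreous *shear* modulus drops out exactly, which
is consistent with the study finding that varying it over 6.5–25 Pa changes
nothing.

### Geometry and its reconstruction

The printed anatomy gives the globe (inner semi-axes 12.36/12.36 mm, shell
thickness 1.0 mm at the poles to 0.5 mm at the equator, blended by the
ellipse-offset construction), the nerve radii (0.85/1.0/1.515 mm) and four
orbit scalars (rim radius 13.95 mm, rim 9.51 mm anterior of the equator
plane, orbit depth 40.26 mm).  Everything else about the orbit is a
reconstruction, and the package treats the following as explicit,
documented modeling choices (defaults in `AnatomyParams`):

* **Wall profile** — rim ring, an equatorial bulge 6 mm lateral of the
  globe, a 1.5 mm outward bow at quarter depth, then a straight cone to the
  apex, truncated where the fat wedge narrows to 1.2 mm.  The bulge and bow
  together put the retrobulbar fat at ~9.1 cm^3, mid-range of MRI fat
  volumetry.
* **Fat anterior boundary** — the fat ends at a ring on the globe at polar
  angle 80 degrees from the posterior pole (just behind the equator, where
  the Tenon/fornix reflection sits) and runs to the orbital wall 3 mm above
  the ring.  The face is a rigid frictionless plane (the fibrous septum):
  fat may slide along it but not cross it.  A ~1.5 mm sliver of the fat
  boundary next to the ring is left untied so the pinched corner can deform
  freely as the globe slides through.
* **Sealed-piston kinematics** — with the wall rigid, the face sealed and
  both fat and vitreous incompressible, the swelling volume must be swept
  by the advancing globe: proptosis is essentially
  `DeltaV_fat / A_piston(w)`, with the piston area the globe cross-section
  at the fat front.  This identity is why fat volume and front-face
  placement dominate the predictions, and why the elastic moduli of the
  fluids barely matter.
* **ICP band** — the intracranial pressure acts on the annulus between the
  axon-bundle radius and the inner dura radius (projected area 0.872 mm^2),
  which reproduces the reported resultants (1.17 mN at 13.6 cmH2O, 1.75 mN
  at 20 cmH2O).  Pressure conversions use the rounded 1 mmHg = 1.36 cmH2O.
* **Muscle ring** — the four recti are lumped into an axial ring tension
  `F = 4M(-0.29 w + 4.79 e^(w/4.57) - 3.01)` mN applied at the polar angle
  115 degrees; `w` is the anterior displacement of that ring measured from
  the terrestrial seating stage.
* **Optic nerve** — never load-bearing: its slack
  (`length - orbit length - AL/2`, threshold 6 mm) is not exhausted in any
  run, so the nerve blocks are geometric only and the fat slides on the
  dural cylinder (radial fixity, axial freedom).

### Staged protocol

1. **Zero-stress search** — cyclic per-parameter secant (coordinate) search
   over the zero-stress semi-axes and the vitreous volume ratio until the
   inflated outer radii match the target within 5 um and the IOP within
   0.05 mmHg.  The IOP target defaults to 15 mmHg (the source never prints
   one).  The radial growth of the chamber (`g_v`, ~91 um at 15 mmHg) is
   reported together with a flag for the published 133–217 um range; the
   value scales with the IOP target.
2. **Residual stress** — the converged inflation is the residually stressed
   eye; it is recentred on the nominal ellipse (a free rigid translation).
3. **Terrestrial seating** — the eye is placed in the orbit in contact with
   unswollen fat; ICP and the muscle multiplier ramp together in five
   steps.  The terrestrial force balance comes out at
   `F_EOM 7.05 ~ F_fat 5.90 + F_ICP 1.15` mN.
4. **Microgravity ramp** — fat hygroscopic strain (and, in the grid driver,
   ICP) are incremented over the published schedule, micro-stepped at
   0.00125 per equilibrium solve.  Only the retrobulbar compartment swells;
   the sliver of pre-septal fat anterior of the rim plane does not take
   part in the fluid shift.  All outputs are microgravity minus
   terrestrial.

### Discretisation and solver

Tensor-product Lagrange quads (order 2 by default, order 4 available) on
structured blocks; axisymmetric total-Lagrangian kinematics, so the exact
tangent is `B^T A B`.  Incompressibility: penalty `kappa = 1e4 mu` with
selective reduced integration for the shell; elementwise mean dilatation
with augmented-Lagrangian pressure multipliers (`kappa = 1e3 mu` inner
penalty) for the fat.  The sclera–fat interface is a frictionless slip tie:
a bilateral penalty on the normal closest-point offset to the
shape-function-subdivided shell surface, with augmented traction
multipliers driving the residual gaps below ~2 um; projections are frozen
within each Newton solve so the line-search energy stays smooth.  Newton
uses an energy (Armijo) line search with a Levenberg–Marquardt fallback;
load steps bisect on failure and a secant predictor warm-starts each step.
Convergence: residual below 1e-8 of the step's initial residual or an
absolute floor of 2 uN (forces in the model are 10^3–10^4 uN).

Numerical tie compliance takes the place of a contact penetration
tolerance; after augmentation the gaps are ~2 um.  The tie is bilateral
(it can transmit tension), which is admissible because the interface stays
compressed throughout the swelling protocol — the reported fat resultant
is anterior-positive at every step.

### Outcome measures

* proptosis: axial displacement of the anterior outer pole;
* axial-length change: pole-to-pole outer extent (an inner-surface variant
  exists);
* peripapillary arc: deformed length of the material segment of inner
  sclera spanning the posterior quarter of the zero-stress circumference
  (1/8 and 1/2 variants available);
* posterior radius of curvature: Pratt algebraic circle fit to the deformed
  outer sclera within 4 mm of the axis, mirrored across the axis;
* axial force balance: muscle law at the realized ring displacement, band
  and tie resultants by boundary summation; the residual is below 0.1% of
  the muscle force at every converged state.

## Problem sizes

Default runs use the coarse mesh (~700 nodes, ~2.6 kDOF): a full 14-point
swelling ramp takes under a minute on one core, and the complete acceptance
computation (baseline plus active-muscle ramp) a few minutes.  Mesh
convergence between coarse and medium is at the percent level for
proptosis; the medium and fine levels are available for verification.

## What the model does and does not reproduce

With the frozen reconstruction the model reproduces: the terrestrial force
balance (7.05 / 5.90 / 1.15 mN against reported ~7.36 / ~5.6 / 1.17 mN);
proptosis along the whole swelling schedule (3.82 mm at 22.5% fat volume
increase, published 4.66 mm, -18%); the maximum muscle force of the
passive ramp (27.5 vs 25.3 mN) and of the doubled-tension ramp (59.9 vs
53.8 mN); the signs and trends of the posterior-curvature and arc-length
changes; the near-null effect of ICP on proptosis; the scleral-stiffness
amplification of all deformation measures with proptosis nearly unaffected;
and the anatomical sensitivity ordering (orbit depth most influential
orbital dimension, equatorial radius most influential ocular dimension,
longer axial length protective).

It does **not** reproduce the printed axial-length change: the model yields
a small *elongation* (+13 um at full swelling) where the source reports
-44 um.  The net axial-length change is a ~10 um residual of four competing
effects — muscle axial squeeze (shortening), posterior fat pressure
(shortening), the swelling-induced IOP rise (elongation), and fat pressure
on the equatorial belt (elongation) — and its sign flips within the
uncertainty of the unprintable fat geometry (moving the fat front a few
degrees around the equator swings it by tens of um).  Raising the muscle
multiplier to 2.25 shifts the model's value by -13 um, the same direction
and order as the published active-tension effect.  The peripapillary-arc
and curvature changes carry the right sign but 3-9 um / 0.08-0.1 mm smaller
magnitudes, correlated with the same pressure-distribution uncertainty.
Two further honest misses: the fat shear modulus is *not* inert here
(doubling it roughly doubles the sub-10-um deformation measures, though
proptosis moves ~1%), and the ICP band — which sits inside the
curvature-fit window, over a canal region this model fills with sclera
rather than nerve tissue — moves the fitted curvature more than an
order-of-magnitude-weak dependence would allow.

## What the synthetic cases show

The preset generator emits the baseline and single-parameter perturbations
(±10% dimensions, scleral modulus 0.25–5 MPa, ICP 0–20 cmH2O, muscle
multiplier to 2.25).  These are idealized axisymmetric anatomies: passing
the suite demonstrates internal consistency of the mechanics and the
robustness of the qualitative findings to the stated parameter ranges, not
subject-specific prediction — real orbits are non-axisymmetric, the recti
are discrete, the septum is compliant, and fat is lobulated rather than a
homogeneous continuum.

## Known limitations

* Axisymmetry: no horizontal/vertical asymmetry, no discrete muscles, no
  fold directionality.
* The orbit wall, fat volume and fat anterior boundary are reconstructions;
  the sub-10-um outputs (axial length, arc) are sensitive to them at their
  own scale.
* The slip tie is bilateral; separation is diagnosed (reported tractions),
  not resolved.
* No viscoelasticity, no fluid transport, no active muscle physiology; the
  multiplier is a static scale on the passive law.
* The optic nerve head/canal region is plain sclera; lamina and nerve-head
  mechanics are out of scope.
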