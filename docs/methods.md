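# Methods

`stentmech` is a desk-scale, reduced-order re-implementation of a
computational stent-evaluation pipeline for left-main (LM) coronary
bifurcation interventions: parametric ring-and-link stent lattices,
hyperelastic/plastic vessel and plaque materials, balloon-driven expansion
with recoil and radial crimping, the standard performance metrics, and a
factorial design comparison with group statistics.

## The fidelity trade-off, stated up front

The reference workflow for this class of problem is explicit-dynamics 3-D
finite element analysis with full contact, hexahedral meshes and
imaging-derived patient anatomies.  `stentmech` replaces all of that with a
per-station (axisymmetric) quasi-static model built from plastic-hinge ring
mechanics and thin-walled composite shells.  The consequence is fundamental
and intentional: **this package reproduces the definitions of the metrics
and the orderings between designs, diameters and plaque classes — not the
absolute newton/millimetre values a commercial solver would produce on real
anatomies.**  Passing tests demonstrate internal consistency and ordinal
agreement with the phenomenology of bench and patient-specific studies on
*synthetic* geometries; they say nothing quantitative about any particular
patient.

## Stent lattices

A design is a stack of zigzag rings (p peaks per ring, 2p strut legs) at
crimped inner diameter 0.84 mm, joined by straight axial links (0.30 mm
default gap).  The four catalog designs carry their printed
characteristics: 9, 10, 12 peaks and 10 peaks with 36/28/50/36 total links,
crimped lengths 19.74/20.62/20.05/20.33 mm, strut thickness 89/89/89/81 µm
(square cross-section by default).  Two derived choices close the geometry:

* **Leg length** comes from a shared fully-open ceiling (7.0 mm diameter by
  default, reflecting the common overexpansion capability of the design
  family): at full opening the chord between adjacent crowns equals the leg,
  `2 r sin(pi/2p) = L`.  More peaks therefore means shorter legs and
  shorter, denser rings.
* **Ring count** is the integer that best fits the printed crimped length
  given that leg length; the residual (at most a few percent) is absorbed
  into the crown height.  This yields 13/15/17/15 rings.

Total link counts are distributed across ring pairs as evenly as possible
with a rotating offset; the per-pair distribution of the real devices is
not public.  Cells (the open faces bounded by struts and links) are
extracted by tracing the rotation system of the graph embedded on the
cylinder; the two faces winding around the axis are the open stent ends.
For a connected lattice the interior cell count equals `E - V`, which for
this construction equals the total link count — the face-count oracle used
in the tests.

Kinematic expansion preserves leg lengths exactly: at radius r the chord is
`c = 2 r sin(pi/2p)` and the crown height `h = sqrt(L^2 - c^2)`, so opening
the crowns foreshortens the stent.

## Materials

Soft tissue uses the incompressible polynomial strain-energy density
`U = sum C_ij (I1-3)^i (I2-3)^j` (all catalog materials are reduced
polynomials, j = 0).  Plaque yields at 34% engineering strain and continues
with a perfectly-plastic plateau (the simplest continuous extension; the
post-yield law is otherwise unspecified).  The five homogeneous plaque
categories span lipid-only to calcium-only behavior with elementwise
increasing coefficients, which guarantees the stiffness ordering at every
strain; the normal arterial wall is a strongly strain-stiffening 6th-order
model.  **All tissue coefficients are documented package defaults shaped to
literature ranges (lipid in the tens of kPa, calcium in the MPa range);
they are not reproductions of any proprietary data set.**  The Pt-Cr stent
alloy is a 1-D elastoplastic hardening law (203 GPa, 480 MPa yield,
hardening to 834 MPa at 45% plastic strain): the hinge solver only ever
sees uniaxial fiber strain, so a multiaxial (Hill-type) plasticity model
would have no observable effect here.  The balloon is a 900 MPa
semi-compliant membrane, 0.05 mm thick.

Strains are engineering strains, stresses nominal, incompressibility exact.
`fit_reduced_polynomial` does linear least squares on the analytic per-term
uniaxial stresses (stress is linear in the coefficients).

## Synthetic vessels

The generator emulates an imaging-derived LM/LAD crossover anatomy on a
station grid (0.2 mm spacing, 64 circumferential sectors): a linear taper
from the proximal reference (≤ 5.0 mm mean diameter) to the distal branch, a
Gaussian mid-segment stenosis whose trough hits the prescribed area
reduction exactly, an eccentric lumen (plaque piled to one side), a normal
wall layer held within 0.1–0.25 mm, a plaque layer filling the gap between
the stenosed lumen and the healthy reference, and a side-branch ostium where
the wall is absent.  Heterogeneous plaque assignment samples OCT-style
morphometrics (lipid/fibrosis/calcium arc fractions from a lipid-leaning
Dirichlet draw, cap thickness, necrotic-core flags) on a coarse grid (every
10th station), interpolates, segments stations into contiguous zones by a
weighted morphometric distance (weights 2/1/1 on thickness and normalized
lipid/calcium arcs, threshold 0.35), and maps each zone to a category by
compositional dominance with a thickness shift.  Everything is driven by a
single seed and bitwise reproducible.

What the generator does **not** emulate: real plaque geometry (no napkin-ring
calcium, no positive remodeling), imaging artefacts, branch-vessel disease,
vessel curvature effects on the mechanics (the solver is axisymmetric per
station).  Tests passing on these vessels show the pipeline is correct and
the orderings robust across the sampled anatomy range — not that any real
lesion behaves this way.

The per-station wall law treats each circumferential sector as a layered
thin-walled shell: each layer contributes its nominal hoop stress at the
local stretch times thickness over current radius (Laplace); sector
pressures average around the circumference.  In the thin-wall linear limit
this reduces to `p = E t u / r^2` (verified within 5%).  The diseased wall
is treated as **pseudo-elastic**: the plateau-softened curve is followed in
both loading and unloading.  This is the package's most consequential
simplification.  Treating plaque unloading as elastic (the plateau replaced
by the yield-point tangent) was implemented and evaluated; it suppresses
recoil so strongly that the per-station model — which has no axial link
coupling to transmit scaffolding support — loses nearly all design
differentiation in expansion.  The pseudo-elastic wall, a standard
simplification in deployment modeling (plaque as compliant nonlinear
tissue), restores the experimentally observed phenomenology: recoil
differentiates ring strength, and expansion differences collapse at both
plaque extremes.

## Deployment solver

Each ring is a closed zigzag of rigid legs joined by elastoplastic crown
hinges.  The crown half-angle is `beta = asin(c/L)`; hinge moment follows a
1-D law with elastic stiffness `k = E I / l_h` (`I = w t^3/12`, effective
hinge length `l_h = 2t`), yield at `M_y = (w t^2/4) sigma_flow`, and
isotropic hardening with hinge strain `kappa t/(2 l_h)`.  Equating hinge
work to pressure work on the ring's tributary shell gives the equivalent
pressure `p_s = 2p M (dtheta/dr) / (2 pi r s0)` with
`dtheta/dr = 4 sin(pi/2p)/h`.  Because the shared-ceiling rule makes
`h/sin(pi/2p)` design-independent, per-hinge mechanics are identical across
designs and the radial-strength ordering emerges purely from hinge density
(2p hinges per ring / s0 axial pitch): the 12-peak design is ~60% stronger
per unit length than the 9-peak, with SYNERGY falling below the 9-peak via
its thinner struts (moment ~ t^3).  Nothing in the code asserts these
orderings; they are consequences measured by the tests.

The balloon applies internal pressure in 50 equal increments to 18 atm
(1 atm = 0.101325 MPa), capped by a semi-compliant membrane radius sized to
reach the target diameter exactly at full pressure; 25 increments deflate
it.  Per increment and station the equilibrium
`P = p_wall(r_out) + p_s(r)` is solved by vectorized bisection to a
1e-6 N force residual (stations capped by the balloon report a zero
residual: the membrane carries the imbalance).  During deflation stations
may only lose radius.  Isotropic hinge hardening is what makes the crimp
hoop force grow with prior expansion diameter, as bench protocols observe.

Radial crimping is displacement-controlled uniform compression of an
expanded stent to (1 − reduction) of its outer diameter (15% default; the
protocol's alternative 4.5→3.5 mm compression corresponds to ~22% and is
available through the `reduction` parameter).  The recorded force is the
holding pressure times the lateral surface; hoop force is total radial
force / 2π.  In the hinge model the force rises monotonically to its
maximum at reverse yield and then declines by a few percent (shrinking
lateral area and growing crown height); the reported quantity — the
maximum — is unaffected.

The recorded friction coefficient (0.2) has no effect: the reduced model
has no axial contact sliding.  It is kept in the configuration for
completeness, not simulated.

## Metrics

* **MSD** — mean of twice the inner stent radius over rings.
* **CCD** — each deployed cell is unrolled onto its mean-radius cylinder
  plane; the largest inscribed circle is the pole of inaccessibility
  (1e-4 mm tolerance) against the strut centerline loop minus the strut
  width; cells over the side-branch ostium are excluded by default.  A
  brute-force grid oracle lives in the test suite only.
* **Prolapse** — per the centroid-radius definition: mean strut outer
  radius minus minimum wall radius per cross-section.  Tissue sag into a
  cell in contact follows a membrane law `d = p_c a^2 / (2 max(T, T0))`
  with `a` the inscribed radius, `T = p_c r` the Laplace wall tension and
  `T0` a physiologic baseline (mean arterial pressure × natural radius);
  sag is capped at the wall's natural position and profiles across the
  cell as a spherical cap.  The state-level default aggregate is the
  maximum over sections (clinically conservative); the mean is also
  reported.  Prolapse uses its own protocol: deployment against the bare
  normal wall, no plaque assignment.
* **SAR** — strut outer surface area (Σ length × width) over the lumen
  surface of the stented segment, as a percentage.
* **Hoop force / radial strength** — hoop force = total outward radial
  force / 2π; normalized by the nominal (crimped) stent length in N/mm;
  radial strength = total radial force / strut outer surface area.  "Total
  stent area" is read as the strut outer surface, consistent with the SAR
  numerator.

## Factorial experiment and statistics

The default cohort crosses 4 designs × 3 diameters (3.5/4.5/5.0 mm) ×
6 plaque modes (five homogeneous + heterogeneous) × 4 geometry seeds = 288
cells, with per-seed anatomical variation (proximal reference 4.2–4.9 mm,
area stenosis 40–70%, eccentricity 0.3–0.7).  The geometry seed is the
experimental unit; summaries are mean ± SEM across seeds, and design
differences are paired within seeds ((a−b)/b × 100%).  Group comparisons
screen normality per group (Lilliefors-corrected Kolmogorov–Smirnov), then
run either one-way analysis of variance with Bonferroni-corrected pairwise
t tests or the Friedman rank test over seed blocks with Dunn's
multiple-comparison test; both branches are explicitly callable.  Failed
solver cells are logged with their residuals and excluded from summaries,
never silently dropped.

The "no material diameter effect on prolapse" finding is operationalized as
a magnitude bound rather than a p-value: the relative spread of mean
prolapse across diameters stays under 15% for every design while the
design effect exceeds twice that.  With a deterministic solver and four
seeds, paired rank tests would flag any consistent effect regardless of
size, so an effect-size criterion is the faithful translation.

## Problem sizes and numerical choices

Default problem sizes — 13–17 rings per stent, 181 stations × 64 sectors
per vessel, 400-point precomputed wall-response tables, 50+25 pressure
increments, 48 bisection iterations, 60-step crimps, the 288-cell cohort —
were chosen so a full cohort completes in minutes on one core while the
oracles (work balance to 1e-6 relative, inscribed circle to 1%, leg lengths
to 1e-9 mm) hold at their stated tolerances.  Ties in cell extraction are
broken by the lexicographic (z, θ) node order; degenerate
(self-intersecting) cell polygons are excluded from CCD with a warning
count on the report row.

## Known limitations

No 3-D contact, no axial link load transfer between rings, no malapposition
or side-branch jailing, no tissue hysteresis or viscoelasticity, no fluid
dynamics, no drug elution or biological response.  The 232-vs-288
simulation-count discrepancy noted in prior factorial work of this type has
no stated exclusion rule; the runner always reports attempted and completed
counts and supports arbitrary factor subsets.
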