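# stentmech

Reduced-order mechanics of coronary stent deployment in synthetic left-main
(LM) bifurcations, for device-design comparison studies.

Left-main interventions need stents that stay strong at large diameters
(up to 5 mm) while scaffolding the lumen densely.  Evaluating a design
family — here ring-and-link everolimus-eluting platforms with 9, 10 or 12
crowns per ring (MEGATRON-style prototypes) against a SYNERGY-style
reference — normally requires vendor CAD, patient imaging and
explicit-dynamics finite element analysis.  `stentmech` implements the same
*comparison pipeline* at desk scale:

* **Materials** — incompressible polynomial hyperelasticity
  `U = Σ C_ij (I1−3)^i (I2−3)^j` for the arterial wall and five plaque
  stiffness classes (lipid-only … calcium-only) with plaque plasticity at
  34% strain; a 1-D elastoplastic Pt–Cr alloy; a 900 MPa semi-compliant
  balloon.
* **Stent lattices** — parametric zigzag rings + axial links reproducing the
  catalog designs' printed characteristics (peaks, links, crimped length
  and diameters, strut thickness), with cell extraction on the cylinder and
  inextensible-strut expansion kinematics.
* **Synthetic vessels** — seeded LM-like bifurcations with a prescribed
  area stenosis, eccentric plaque, a 0.1–0.25 mm normal wall layer, and
  homogeneous or OCT-morphometric-style heterogeneous stiffness zones.
* **Deployment solver** — balloon inflation to 18 atm, recoil and radial
  crimping, with each ring modeled as elastoplastic crown hinges in
  per-station equilibrium against the layered wall
  (`p_s = 2p·M·(dθ/dr)/(2πr s0)`).
* **Metrics** — mean stent diameter (MSD), circular cell diameter (CCD,
  largest inscribed circle per cell), vessel prolapse, stent-artery ratio
  (SAR), normalized hoop force (radial force / 2π / length) and radial
  strength.
* **Experiment** — a 4 × 3 × 6 × n-geometry factorial runner with
  mean ± SEM summaries, ANOVA/Bonferroni and Friedman/Dunn comparisons.

This is a reduced-order model: it reproduces metric **definitions and
orderings** (which design expands more, scaffolds better, resists crimping
harder, and how plaque stiffness modulates that), not the absolute values
of a 3-D contact simulation.  See `docs/methods.md` for the model, its
assumptions and its limits.

## Worked example

Deploy the 12-peak design at 4.5 mm into a synthetic neutral-plaque
bifurcation (geometry seed 0) and print its metrics:

```sh
$ stentmech simulate --design MEGATRON_12 --diameter 4.5 --plaque neutral --seed 0
design: MEGATRON_12
diameter: 4.5
plaque_mode: neutral
geometry_seed: 0
msd: 4.049174739656419
ccd: 0.9317394584159628
prolapse: 0.054575283823624164
prolapse_mean: 0.03386348080492211
sar: 15.33840529558188
normalized_hoop_force: 0.12687449484749536
radial_strength: 0.4641902989436815
degenerate_cells: 0
```

Reading: the stent recoiled from the 4.5 mm balloon target to a mean inner
diameter of 4.05 mm against the neutral-stiffness lesion; the mean largest
circle fitting through a cell is 0.93 mm (smaller = denser scaffolding);
tissue protrudes at most 0.055 mm between struts; struts cover 15.3% of the
stented lumen; the retained outward force corresponds to 0.127 N/mm of
stent length.  The same call with `--design MEGATRON_9` gives a smaller
MSD, larger CCD and prolapse, and lower hoop force — the peak-count
dose–response the pipeline exists to measure.

The bench-style crimp test (free expansion to 4.5 mm, then 15% radial
compression):

```sh
$ stentmech bench-crimp --design MEGATRON_12 --diameter 4.5
MEGATRON_12 expanded to 4.5 mm, crimped by 15%: max hoop force 6.796 N, normalized 0.3390 N/mm
```

A factorial run from a YAML config (see `stentmech run --help`) writes a
tidy `results.csv`, per-metric mean ± SEM summaries and grouped bar figures.

Library use mirrors the CLI:

```python
from stentmech import (DESIGN_CATALOG, expand_stent, compute_metrics,
                       generate_bifurcation, assign_homogeneous_plaque)
vessel = assign_homogeneous_plaque(generate_bifurcation(seed=0), "soft")
state = expand_stent(DESIGN_CATALOG["MEGATRON_12"], vessel,
                     target_inner_diameter=4.5)
print(compute_metrics(state, plaque_mode="soft").row())
```

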