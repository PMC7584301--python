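# dressfea

Finite-element analysis of prophylactic silicone-foam dressings under
combined compression and shear, with volume-weighted strain-energy-density
(SED) quantification.

## The problem

Pressure injuries form where soft tissue is trapped between a bony
prominence and a support surface — classically at the sacrum when a
patient lies with the head of the bed elevated 45° (Fowler's position),
which loads the tissue in combined compression and caudal shear.
Prophylactic foam dressings are placed over the sacrum to redistribute
this load.  `dressfea` models a sagittal section of the loaded sacral
region — mattress, optional dressing, soft tissue with an embedded
rigid bony prominence — and asks: *how much does each commercial
dressing reduce the tissue volume exposed to damaging strain energy
densities, relative to no dressing?*

The package is for biomechanics researchers and medical-device engineers
who want a transparent, tested, scriptable re-implementation of this
comparison pipeline: meshing, nonlinear FE solution, contact with
friction, SED histograms, and the dressing-versus-control report.

## The model in brief

* Soft tissue: nearly incompressible neo-Hookean,
  W = G/2 (I₁ − 3) − G ln J + λ/2 (ln J)², with G = 19.254 kPa,
  K = 1919.022 kPa (ν = 0.495).
* Bone: rigid driver (linear elastic E = 3.4 GPa, ν = 0.36 available);
  mattress: foam block, E = 50 kPa, ν = 0.3.
* Dressings: homogenized compressible neo-Hookean foams whose
  small-strain modulus equals the effective modulus identified from
  flat-punch indentation (nine commercial parameter sets packaged).
* Loading: the bone is displaced 45° caudally from the mattress normal
  until the mattress reaction reaches 40 N (±0.1 N), with penalty
  contact and Coulomb friction (μ = 0.4 dressing–mattress; μ = 0.7 for
  bare skin in the control) at the support interface.
* Outcome: per-element SED over the tissue, binned volume-weighted on
  0.05–1.0 kPa, pooled at the 0.5 kPa damage threshold, and

      %SED reduction = (AUC_control − AUC_dressing)/AUC_control × 100.

See `docs/methods.md` for the full model description, parameter
rationale, and limitations of the 2-D idealization.

## Worked example

Identify a dressing modulus from synthetic indentation curves, then
solve the control scenario:

```python
import numpy as np
from dressfea import (
    generate_indentation_curves, effective_modulus_from_curve,
    conservative_modulus, generate_scenario_suite, run_case,
    reaction_force, sed_field,
)

# bench protocol: 3 locations x 5 samples, 3 % force noise
curves = generate_indentation_curves(19.0, 5.50, noise_cv=0.03, seed=7)
moduli = [effective_modulus_from_curve(c).modulus for c in curves]
print(f"TSF effective modulus: {np.mean(moduli):.1f} kPa "
      f"(conservative minimum {conservative_modulus(moduli):.1f} kPa)")

suite = generate_scenario_suite()
control = run_case(suite, suite.case("no_dressing"))
R = reaction_force(control, "mattress_base")
sed = sed_field(control, "tissue")
print(f"reaction {np.linalg.norm(R):.2f} N, peak tissue SED {sed.max():.2f} kPa")
```

Output:

```
TSF effective modulus: 18.9 kPa (conservative minimum 18.6 kPa)
reaction 40.00 N, peak tissue SED 1.51 kPa
```

The conservative minimum is the rule used for the FE comparison: the
lowest modulus observed across all replicates.  The control's tissue SED
peaks just above 1 kPa at the prominence tip — well above the 0.5 kPa
potential-damage threshold.

The same stages are available from the shell:

```sh
dressfea simulate -o out/           # synthetic indentation curves
dressfea indent out/curves_TSF.csv -o out/
dressfea solve --case TSF -o out/   # one scenario, VTK + contour export
dressfea compare -o out/            # ten-case suite -> reduction report
```

`dressfea compare` writes `sed_reduction_report.csv` with the schema
Dressing / Foam stiffness (kPa) / Foam thickness (mm) / % SED reduction
in total / of <0.5 kPa / of ≥0.5 kPa.

## Mesh text format

`dressfea mesh` writes a plain-text mesh (and legacy VTK):

```
dressfea-mesh <dim> <n_nodes> <n_elements> <out_of_plane_thickness>
node <id> <x> <y>
element <id> <region> <n0> <n1> <n2> <n3>
surface <name> <count> <id ...>
```

Regions are `bone`, `tissue`, `dressing`, `mattress`; named surfaces
include `mattress_base`, `mattress_top`, `dressing_bottom`,
`dressing_tissue_interface`, `bone_nodes`.

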