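# Methods

`dressfea` models the biomechanical protection that a prophylactic
silicone-foam dressing offers to the soft tissue over the sacrum when a
patient lies in a 45° semi-seated (Fowler's) position, and quantifies it
as the reduction in volume-weighted strain energy density (SED) relative
to lying on the mattress with no dressing.

## Model

The domain is a sagittal plane-strain section of a layered stack: a foam
mattress block, an optional foam dressing bonded to the skin, and a soft
tissue block containing a rigid, lens-shaped bony prominence (the sacral
apex).  Coordinates: x caudal along the mattress surface, y normal to
it, origin at the mattress-base corner; lengths in mm, stresses and
moduli in kPa.

**Materials.**  Soft tissue is nearly incompressible neo-Hookean with
shear modulus G = 19.254 kPa and bulk modulus K = 1919.022 kPa
(ν = 0.495); "incompressible" is realized through the large bulk
modulus, not a mixed formulation.  Bone is linear elastic (E = 3.4 GPa,
ν = 0.36) but is driven rigidly by default — all bone-region nodes share
the prescribed displacement — because it is ~10⁵× stiffer than tissue.
The mattress uses E = 50 kPa, ν = 0.3; we give it the neo-Hookean family
because it sustains compressive strains well beyond the small-strain
regime (a geometrically linear branch is selectable).  Each dressing is
a homogenized compressible neo-Hookean solid whose small-strain Young's
modulus equals the effective modulus identified by flat-punch
indentation, with a foam Poisson ratio of 0.1 (configurable; foams are
strongly volume-compressible).  The 2 % solid volume fraction of the
foam is carried as metadata on the material: with no poroelastic
constants available (permeability, fluid phase), a biphasic model would
be unidentifiable, so the homogenized solid is the model, not a proxy.

The compressible neo-Hookean energy is the classical form
W = G/2 (I₁ − 3) − G ln J + λ/2 (ln J)², which reduces to linear
isotropic elasticity with the same (G, λ) at small strain.

**Elements and incompressibility.**  Bilinear quadrilaterals in a
total-Lagrangian setting with analytic first-elasticity tangents.  For
neo-Hookean regions the λ-term (volumetric penalty) is integrated at the
element midpoint and the G-terms at 2×2 Gauss points — selective reduced
integration, which prevents volumetric locking at ν = 0.495 while the
full-rank G-term quadrature suppresses hourglassing.  Element SED and
Cauchy stress are volume-weighted quadrature averages; the out-of-plane
stress σ₃₃ is carried so the von Mises (distortional) stress is the true
3-D deviatoric measure.

**Contact and friction.**  The body (dressing underside, plus any bare
skin) meets the mattress top through node-to-segment penalty contact.
The normal pressure is linear in penetration with a C1 quadratic ramp
over the first 10⁻³ mm of engagement (working penetrations are one to
two orders larger); without the ramp, Newton iterations stall on the
stiffness jump at grazing contact.  Coulomb friction uses the standard
tanh regularization t = −μp·tanh(k_t s/μp) of stick-slip: stick
stiffness k_t at zero slip, saturation exactly at the Coulomb cone.
Stick anchors are material points on the master surface, dragged along
it at the end of each converged load step once the regularized traction
reaches ~99.5 % of the cone (tanh argument 3).  Penalties default to
50× the softer neighbor's modulus per element length.  Bulk element
tangents are analytic; each contact node's local tangent (≤ 10 dof) is
built by central differences of the exact local force, which is accurate
to ~10⁻⁷ on the smooth branches.

**Loading.**  No gravity or body force: the bone is displaced along a
direction 45° caudal from the mattress normal, and a safeguarded secant
iteration on the displacement scale (with state continuation, automatic
substepping, and back-off on nonconvergence) finds the scale at which
the mattress-base reaction reaches 40 N magnitude within 0.1 N.  The
mattress base is fully fixed; the lateral and superior faces of the
tissue and mattress blocks are traction-free.

## Geometry of the reference scenario

The tissue block (200 mm wide × 75 mm high in the sagittal section)
sits on a mattress block of the same footprint, 75 mm thick.
Geometric choices the source model leaves open are set as follows and
are deliberate parts of the packaged study conditions:

* **Prominence.**  A lens-shaped rigid inclusion embedded in the tissue,
  bounded below by a cosine² bump whose curvature at the apex equals the
  tip radius (default 5 mm — the "tight radius" regime that
  concentrates stress), with 10 mm of tissue cover between the tip and
  the skin (soft tissue over a loaded sacrum is thin).  Tissue lies both
  under and above the bone, so the overlying tissue rides with the bone
  instead of being sheared against a free surface.
* **Convex skin.**  The skin under the prominence bulges toward the
  mattress (default 12 mm over a 60 mm half-width).  In the bare control
  only the apex region initially touches; support is recruited
  progressively as the skin flattens into the mattress.  This is the
  contact regime in which a dressing can bridge load away from the
  prominence — with a flat skin, flat-on-flat contact leaves a foam
  layer almost nothing to redistribute.
* **Effective depth.**  Plane-strain line forces are converted to
  newtons through an effective out-of-plane width of 50–90 mm (default
  in `DomainSpec`), the width of the sacral apex region that actually
  bears the load — not the full 250 mm block depth, over which a 2-D
  section would unrealistically dilute the 40 N.  The value is
  calibrated so the control's SED field peaks slightly above 1 kPa,
  matching the analyzed 0.05–1.0 kPa range of the study design.
* **Friction.**  The dressing-mattress interface uses the "somewhat
  sticky" μ = 0.4.  In the control the skin itself rests on the
  mattress; skin on textile/foam supports is stickier, and we default
  that interface to μ = 0.7 (configurable).  Part of a silicone
  dressing's benefit is replacing this high-friction interface.
* **Dressing footprint.**  Full block width by default.  The bordered
  sacral dressings are of comparable extent, and in a 2-D section a
  partial band leaves the neighboring skin hanging one foam thickness
  above the mattress, funneling the entire load through the band — a
  plane-strain artifact, not a feature of the 3-D original.

The mesh is boundary-fitted to the lens and the skin bulge by per-column
node snapping (no voxel staircase at the tip), laterally graded from
~1.7 mm elements under the tip to ~6.7 mm at the block edges, with
tissue rows biased toward the cover region.  The default production
resolution is 0.15 elements/mm (~900 elements); all ten comparison cases
share the tissue mesh topology exactly, so per-element fields are
directly comparable.

## Indentation analysis

A flat-ended cylindrical punch (6 mm diameter, 1 mm/s, to 50 % of layer
thickness) on a bonded elastic layer has initial stiffness
dF/dδ = 2aE/(1 − ν²)·κ(a/t), with the Shull-type bonded-layer
confinement correction κ = 1 + 1.33(a/t) + 1.33(a/t)³ (κ = 1 recovers
the half-space; for these dressings a/t ≈ 0.4–0.9, far from a
half-space).  The effective modulus comes from a least-squares slope
over the 5–25 % compression window, which avoids both toe-in seating
artifacts and large-strain stiffening.  The conservative rule takes the
minimum modulus over all replicates (three locations × five samples per
dressing type).  The synthetic generator uses the same forward relation
with optional large-strain stiffening (off by default) and multiplicative
Gaussian force noise (CV 3 % by default) — so noise-free round trips are
exact by construction, and noisy recovery tests measure the estimator,
not model mismatch.

## Quantification

Per-element SED over the soft-tissue region is binned into a
volume-weighted histogram on the analyzed range 0.05–1.0 kPa, 19 uniform
bins of 0.05 kPa — this bin width places the 0.5 kPa potential-damage
threshold exactly on a bin edge, which the pooling step requires.
Volume below/above the range is tracked separately; the "≥ 0.5 kPa" pool
includes above-range volume at one bin width (it is tissue at damaging
SED), while below-range volume lies outside the analyzed range entirely.
Pool AUC is the rectangular area Σ volume × bin width, and

    %SED reduction = (AUC_control − AUC_dressing)/AUC_control × 100

per pool and in total.  Reference (undeformed) element volumes are the
default weights; deformed volumes are available.  "Distortional (shear)
stress" is the von Mises equivalent stress (Tresca selectable).

## What the synthetic data do and do not show

The generators reproduce the study's design: the nine commercial foam
parameter sets, the indentation protocol with known ground truth, and a
shared-geometry ten-case suite (nine dressings + control) at 40 N / 45°
with 0.4 dressing-mattress friction.  They do not emulate subject MRI
geometry, tissue heterogeneity, 3-D load redistribution around the
sacrum, dressing multilayer anisotropy, or time effects — so passing
tests demonstrate correctness of the mechanics and statistics pipeline
and qualitative reproduction of the dressing-protection effect in a 2-D
section, not subject-level prediction.

A genuine limitation of the plane-strain section: an added compliant
layer increases the bone travel needed to reach the target force, and in
2-D that extra travel strains a larger mid-field volume into the low end
of the analyzed band than it does in 3-D, where load also redistributes
out of plane.  On the packaged scenario the high-SED pool (≥ 0.5 kPa),
which tracks the damage-relevant concentration at the prominence,
reproduces the expected dressing benefit in sign for every dressing, and
every dressing lowers the peak tissue SED; the low pool — and with it
the total, which the low pool dominates — can come out negative, i.e.
the 2-D section overstates the mid-field strain cost of the dressing's
compliance.  Low-pool and total reductions from this model should
therefore be read as conservative (biased against the dressing), while
high-pool reductions are the robust comparative statistic.

## Numerical choices

* Newton: relative residual 10⁻⁶ (reference: max of reaction and
  external force norms), up to 60 iterations, backtracking line search,
  load-step bisection to depth 5.
* Force target: 0.1 N tolerance on the 40 N reaction magnitude.
* Contact: penalty 50×E_soft/h; C1 engagement ramp 10⁻³ mm; tanh
  friction with anchor drag at argument 3.
* Histograms: 19 × 0.05 kPa bins on [0.05, 1.0] kPa.
* Degenerate inputs: inverted elements raise errors carrying the element
  id during assembly, and are reported (not raised) as non-positive
  Jacobians by mesh quality checks.
* Mesh: per-column snapping keeps all quadrilaterals convex; quality is
  checked at Gauss and corner points.

## Known limitations

Plane-strain idealization of a 3-D contact problem (see above); rigid
bone driver (deformable bone supported but not default); homogenized
single-layer dressings; no viscoelasticity or poroelastic fluid phase;
penalty contact admits penetrations at the compliance scale
(~10⁻² mm); the skin-mattress friction coefficient of the bare control
is a literature-informed choice, not a measured value from the source
study.
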