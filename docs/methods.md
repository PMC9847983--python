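# Methods

## Model and assumptions

`reefflow` treats the reef benthos as a submerged canopy of identical
colonies in steady, current-dominated flow. A momentum balance between the
driving hydraulic gradient over depth H and the quadratic drag of the
canopy yields

- per-colony drag F_D = ½ φ ρ C_D Af U_c²,
- drag per unit reef area and unit density f_D = ½ φ C_D λf U_c²,
- slope-driven in-reef velocity U_c = √(2 φ g H S / (C_D λf)),
- canopy-top shear velocity u\* = √(g (H − h) S),

and, with the shear-layer closure u\* ≈ k ΔU, the attenuation ratio

    β = U∞ / U_c = 1 + k* √(C_D α),    α = (λf / φ)(1 − h/H).

Assumptions: flow is steady and unidirectional (oscillatory attenuation is
weaker and not modelled); the canopy is horizontally homogeneous at reef
scale, so a single colony plus its share of reef area (Ap / cover)
represents the array; β is evaluated as a horizontally- and depth-averaged
ratio, so wake-scale horizontal variability is averaged out; the drag
coefficient is Reynolds-independent over field-scale flows, which makes β
independent of U∞ itself.

The slope-driven U_c is implemented with φ in the numerator, and α with φ
in the denominator, as one consistent chain: the closure test asserts
g H S = ½ (C_D λf / φ) U_c² to 1e-12 relative. The coefficient k* is kept
as a free order-one coefficient; when derived from the shear coefficient k
it uses k* = 1/(2k), with the alternative algebraic form 1/(√2 k) noted in
output metadata.

## Parameters

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| C_D | colony drag coefficient | – | 1.0 | measured reef values cluster in 0.5–2; a constant avoids an unpredictable per-morphology input |
| k* | shear coefficient in β | – | 1.0 | the fitted β–α collapse is close to β − 1 = √α |
| ρ | water density | kg m⁻³ | 1000 | fresh-water flume scale; override for seawater |
| g | gravity | m s⁻² | 9.81 | – |
| cover | colony plan area / reef area | – | user input | the survey quantity that sets λf linearly |
| φ | canopy-box porosity | – | user input / measured | never bundled with presets (archetype porosities are not tabulated) |
| raster resolution | silhouette/voxel cell size | m | extent/100 | <1% error on analytic fixtures; halving changes results <0.5% |

## Morphometric conventions

- **Frontal area Af**: Σ over faces of max(0, −n̂·d̂)·area, flow along +x
  after azimuth rotation. This is the only closed-surface formulation
  consistent with every tandem element adding drag; it needs no branch
  segmentation. Downstream faces contribute zero (not negative) area; for a
  convex body the face sum equals the silhouette, and for tandem bodies it
  exceeds it — both are asserted in tests.
- **Plan area Ap**: union of face projections onto the horizontal plane,
  rasterised at the requested cell size with a 4×4 sub-cell coverage
  sample. The rasteriser is cross-checked in tests against an exact
  shapely polygon union.
- **Volume**: divergence-theorem (signed tetrahedron) sum for watertight
  meshes; otherwise vertical-column even-odd integration at the raster
  resolution (exact in z, discretised in xy). Columns with an odd crossing
  count are closed against the bed plane, which handles scans that are open
  at their base; coincident internal interfaces of touching closed
  sub-solids are merged by the crossing dedupe, so multi-part solids should
  use the divergence route (they are watertight, so they do by default).
- **Porosity φ**: 1 − V/(footprint × h), clamped to [0, 1]. The box
  footprint defaults to the colony's axis-aligned plan bounding rectangle
  in the as-digitised (θ = 0) frame, keeping φ a colony property
  independent of cover, as the per-colony drag law requires; a plan
  convex-hull footprint is available (`phi_box="plan-hull"`) and the
  convention is recorded in every output.
- **Height h**: full vertical extent of the colony, standing in for the
  average benthos height in single-morphology scenes.
- Azimuth convention: θ = 0 is the as-digitised orientation (narrow end of
  the massive form into the flow); `rotate_to_azimuth` rotates by −θ about
  z so flow is always +x.

## Synthetic morphologies

The generators emulate the three archetypes with solids whose geometry is
closed-form: branching = a square grid of vertical 32-gon prisms
(defaults: 9 branches, 1 cm diameter, 5.6 cm tall, 3 cm spacing); massive =
a hemiellipsoid (4 × 3 × 5.1 cm semi-axes, narrow side into the flow at
θ = 0); table = a polygonal plate (5 cm radius, 8 mm thick) on a cylindrical
stem (total height 3.4 cm). Dimensions follow the centimetre scale of the
digitised colonies used in laboratory and LES canopy-flow studies; heights
match the tabulated archetype heights. Oracles use the exact polygon areas
and widths of the generated cross-sections, so prism fixtures agree with
the mesh pipeline to machine precision and only the curved massive form
carries surface-discretisation error (≈0.4% at the default 32-segment
resolution, ≈0.1% at 64). Branch jitter is off by default and seeded when
enabled. What the generators do *not* emulate: scan noise, open surfaces,
branch tapering and anastomosis, or mixed assemblages — passing tests
bound numerical error against known geometry, not biological realism.

The attenuation-dataset generator draws β = 1 + c√α + ε with seeded
Gaussian ε and clips at the physical floor β = 1. Its default study design
in tests and the acceptance script — 21 scenes spanning α = 0.05–2.5 with
σ = 0.25 scatter — mirrors the size and scatter of a canopy-resolving
simulation campaign across morphology, cover, depth, orientation and
velocity.

## Fitting

`fit_attenuation` estimates c in (β − 1) = c√α by through-origin least
squares in transformed coordinates (y = β − 1 on x = √α), enforcing the
physical anchor β(0) = 1; R² is reported on β − 1 about its mean, so a fit
can score below zero if it is worse than the mean line. The 95% prediction
interval uses normal quantiles on the residual standard deviation
(1.96 σ √(1 + α/Σαᵢ)) and is documented as approximate. A design with a
single distinct α raises a rank error.

## Numerical choices and degenerate inputs

- Raster cells are occupied by sub-sample centre-in-triangle tests with a
  1e-9 barycentric tolerance; edge-on faces (zero projected area) are
  skipped.
- Resolution precondition: cell size ≤ 1/20 of the smaller horizontal
  extent; the default is 1/100 of the larger extent.
- Non-watertight loads are accepted and flagged; closed meshes with
  inconsistent winding raise an orientation error, and inward-pointing
  closed meshes are flipped at load.
- Degenerate porosity inputs (zero height or footprint) raise a validation
  error; β floors at exactly 1 for α = 0; λf = 0 under slope forcing raises
  (unbounded velocity).
- Problem sizes throughout tests and the acceptance script are desk-scale:
  meshes of ~10²–10⁴ faces, 100-cell rasters, 200 fit replicates.

## Limitations

- The framework omits skin friction on plate-like surfaces, so table-form
  attenuation at high cover is under-predicted unless C_D is raised; C_D is
  otherwise held at 1 across morphologies.
- Mixed assemblages are handled by summing frontal areas into λf, but the
  effective φ of a mixture must be supplied by the user.
- β is a horizontally averaged prediction; local velocities inside wakes
  and gaps deviate strongly from U_c.
- Archetype presets carry geometry only; porosity must come from the mesh
  pipeline or the user.
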