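# reefflow

Flow velocities inside a coral reef canopy are much lower than at the water
surface, and that in-reef flow controls nutrient uptake, heat flushing,
larval settlement and sediment transport. `reefflow` predicts the
attenuation of steady currents by a reef benthos from geometry alone, and
computes the colony-scale morphometrics that feed the prediction from 3-D
triangle meshes of individual coral colonies. It is aimed at reef
ecologists, coastal engineers and restoration planners who have (or can
approximate) colony geometry and want a first-order in-reef velocity
without running canopy-resolving CFD.

## The model

The attenuation ratio β = U∞ / U_c compares the near-surface velocity U∞
with the horizontally- and depth-averaged in-reef velocity U_c (β ≥ 1).
Balancing the driving hydraulic gradient against quadratic canopy drag
gives a single geometric predictor:

```
λf = cover · Af / Ap                 frontal area index
α  = (λf / φ) · (1 − h / H)          attenuation predictor
β  = 1 + k* · √(C_D · α)             attenuation ratio
```

where, per colony, `Af` is the frontal area (the **sum** of the projected
areas of all upstream-facing surfaces — every branch along the flow line
adds drag, with no occlusion removal), `Ap` the plan area (occlusion-removed
silhouette from above), `h` the colony height, `φ` the porosity of the
canopy-height bounding box, `H` the water depth, and `cover` the fraction of
reef plan area occupied by colonies. `C_D` is an order-one drag coefficient
(default 1 for all morphologies) and `k*` an order-one shear coefficient
(default 1). β → 1 as the frontal area vanishes or the canopy emerges
(h → H), is independent of the flow speed itself, and the collapse
(β − 1) = c·√α with c = k*·√C_D can be fitted to data with
`fit_attenuation`.

Slope-driven forcing is also supported: U_c = √(2 φ g H S / (C_D λf)) and
the canopy-top shear velocity u\* = √(g (H − h) S).

Three archetypal colony forms ("table" — a plate on a stem, "massive" — a
monolithic mound, "branching" — an array of thin vertical elements) ship
both as measured geometric presets and as parametric mesh generators with
closed-form oracles, so the whole pipeline runs without external data.

## Worked example

```python
from reefflow import DragModel, ReefScene, get_preset, predict_flow

preset = get_preset("branching")
scene = ReefScene(cover=0.20, Af=preset.Af_cm2(0), Ap=preset.Ap_cm2,
                  phi=0.90, h=preset.h_m, H=0.16)
pred = predict_flow(scene, U_inf=0.16, drag=DragModel())
```

prints (via `python examples/predict_attenuation.py`):

```
frontal area index lambda_f = 0.299
predictor alpha             = 0.216
attenuation ratio beta      = 1.465
in-reef velocity U_c        = 0.109 m/s (from U_inf = 0.16 m/s)
```

At 20% branching cover in 0.16 m of water, the canopy carries λf ≈ 0.30 of
frontal area per unit reef area; the predictor α ≈ 0.22 gives β ≈ 1.47, so a
0.16 m/s surface current drops to ≈ 0.11 m/s inside the canopy. The other
scripts in `examples/` measure a synthetic colony mesh, fit the β–α
collapse to scattered data, and tabulate cover → λf/φ allometric curves.

The same operations are available from the shell:

```sh
reefflow synth --archetype branching --out colony.stl --oracle oracle.json
reefflow measure colony.stl --theta 0,45,90
reefflow predict --cover 0.2 --archetype branching --phi 0.9 --depth 0.16 --u-inf 0.16
reefflow fit pairs.csv
reefflow allometry --archetype massive --phi 0.9 --covers 0.05:0.5:0.05 --fmt csv
```

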