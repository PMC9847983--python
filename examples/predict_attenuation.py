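"""Predict in-reef flow attenuation for a reef scene.

Uses the bundled branching-colony geometry at 20% coral cover in 0.16 m of
water with a 0.16 m/s near-surface current, and prints the attenuation
chain: lambda_f -> alpha -> beta -> U_c.
"""

from reefflow import DragModel, ReefScene, get_preset, predict_flow

preset = get_preset("branching")
scene = ReefScene(
    cover=0.20,
    Af=preset.Af_cm2(0),        # cm^2; only the Af/Ap ratio matters
    Ap=preset.Ap_cm2,
    phi=0.90,                   # porosity is a user input, not tabulated
    h=preset.h_m,
    H=0.16,
)
pred = predict_flow(scene, U_inf=0.16, drag=DragModel())

print(f"frontal area index lambda_f = {scene.lambda_f:.3f}")
print(f"predictor alpha             = {pred.alpha:.3f}")
print(f"attenuation ratio beta      = {pred.beta:.3f}")
print(f"in-reef velocity U_c        = {pred.U_c:.3f} m/s (from U_inf = 0.16 m/s)")

# beta = 1 + sqrt(alpha) with C_D = k* = 1: the in-reef flow is U_inf / beta.
# beta depends only on geometry (cover, morphology, depth), not on U_inf.
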