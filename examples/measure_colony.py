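"""Measure the morphometrics of a coral colony mesh.

Generates a synthetic branching colony (a 3x3 array of 1-cm branches,
5.6 cm tall), measures it through the same pipeline a scanned colony would
take, and compares against the generator's closed-form geometry.
"""

from reefflow import SyntheticColonySpec, generate_colony, measure_colony

mesh, oracle = generate_colony(SyntheticColonySpec(archetype="branching"))
geom = measure_colony(mesh, thetas=[0.0, 45.0, 90.0])

print(f"height h          : {geom.h * 100:.2f} cm")
print(f"plan area Ap      : {geom.Ap * 1e4:.2f} cm^2   (closed form {oracle.Ap * 1e4:.2f})")
print(f"frontal area Af(0): {geom.Af(0.0) * 1e4:.2f} cm^2   (closed form {oracle.Af0 * 1e4:.2f})")
print(f"solid volume      : {geom.V_solid * 1e6:.2f} cm^3")
print(f"porosity phi      : {geom.phi:.3f}")

# Af is the summed projected area of every upstream-facing surface, so each
# branch down the flow line adds to it; Ap removes overlap (seen from above).
# The porosity treats the colony as a box from the bed to z = h.
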