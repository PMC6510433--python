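"""From a naming model to the categorical geometry of the cube.

Takes the 13-name demo model, blurs its normalized distribution field,
pre-computes the metric tensor grid (21^3 nodes at spacing 0.05), and
measures the standard sub-manifolds: the achromatic axis and full colour
locus in grains, and the capacity of the whole cube (how many
categorically distinct colour regions it holds under this model).
"""

import catmetric as cm

model = cm.demo_model()
field = cm.blur_field(model.field(), delta=0.1)
grid = cm.tensor_grid(field, spacing=0.05, delta=0.1)

axis = cm.path_length(grid, cm.achromatic_axis())
locus = cm.path_length(grid, cm.full_colour_locus())
print(f"achromatic axis: {axis['grains']:.2f} grains "
      f"-> capacity {cm.capacity(axis['grains'], 2, dim=1):.2f}")
print(f"full colour locus: {locus['grains']:.2f} grains "
      "(closed, so capacity equals its length)")

cap = cm.cube_capacity(grid, resolution=20)
print(f"cube volume {cap['volume_grains']:.2f} volumetric grains, "
      f"boundary area {cap['boundary_area_grains']:.2f} areal grains")
print(f"capacity of the full cube: {cap['capacity']:.1f} categorically "
      "distinct regions under the 13-name demo model")
print("(a population model with hundreds of names articulates colour "
      "space much more finely)")
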