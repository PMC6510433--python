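"""Toy 1-D colour manifolds: categorical length, capacity and warp.

Builds the three toy category systems (broad chromatic names; narrow
low-peak tonal names; both together), runs each through the sqrt-sphere
pipeline, and prints the categorical extent in grains, the capacity
(distinct-colour count, boundary-corrected) and the variability of the
local metric.  Adding tonal categories increases the capacity but evens
out the metric (smaller sd of log2 metric).
"""

import catmetric as cm

for label, spec in [("chromatic only", cm.chromatic_spec()),
                    ("chromatic + tonal", cm.combined_spec()),
                    ("tonal only", cm.tonal_spec())]:
    res = cm.toy_manifold(spec)
    print(f"{label:18s} length {res['grains']:.2f} grains | "
          f"capacity {res['capacity']:.2f} distinct colours | "
          f"sd log2(metric) {res['sd_log2_metric']:.2f}")

print()
print("A 1-D manifold of extent 1.7 grains with two endpoints holds "
      f"{cm.capacity(1.7, boundary_grains=2, dim=1):.1f} distinct colours "
      "(each end region needs only half the usual extent).")
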