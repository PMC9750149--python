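"""Estimate limb thickness from all cells and render maps.

Pooling every collected cell into one group and inferring its sbin
distribution gives, after dividing by sbin areas, a relative thickness
profile of the tissue.  The map rendering writes a PNG of the profile on
the limb outline (AER arc in red).
"""

import numpy as np

import tattooseq as tq
from tattooseq.io import render_map

model = tq.LimbModel.build()
cfg = tq.SimulationConfig(seed=3, n_limbs_per_pattern=3,
                          n_cells_per_limb=3000, n_genes=20, n_spatial=0)
facs, _, truth = tq.simulate_limb_dataset(cfg, model)
calls = tq.call_colors(facs, seed=3)

thick, post = tq.infer_thickness(calls, model.grid.forward,
                                 model.grid.areas, seed=3)
coords = model.sbin_coords()
order = np.argsort(coords["pd"])
print("sbin thickness (normalized to max 1), flank -> tip:")
for i in order:
    print(f"  sbin {i:2d}  pd={coords['pd'][i]:.2f}  "
          f"thickness={thick[i]:.2f}")
print("\nThe profile decreases from the flank toward the distal tip, "
      "matching the generating half-ellipse cross-section.")

render_map(post.theta, model, path="thickness_map.png", density=True,
           title="cell density per unit area")
print("wrote thickness_map.png")
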