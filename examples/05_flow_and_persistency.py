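"""Measure ER movement by optical flow and find persistent anchors.

A movie is generated with bulk translation (cytoplasmic-streaming
style) plus jitter, while EPCS-like anchor puncta stay fixed.  Dense
Farnebäck flow recovers the imposed velocity; the temporal-median
persistency analysis recovers the anchors.
"""

import numpy as np

from erquant.flow import farneback_flow, summarize_flow
from erquant.persistency import persistent_nodes
from erquant.synth import animate_scene, generate_network_scene

stack, truth = generate_network_scene(n_polygons=30, cisterna_fraction=0.0,
                                      noise_sd=0.01, n_anchors=4, seed=3)
v = 2.5 * stack.pixel_size_nm / 1000.0 / 0.41     # 2.5 px/frame
mov, mt = animate_scene(truth, 30, translation_um_s=(v * 0.6, v * 0.8),
                        jitter_sd_px=0.5, anchor_pin_radius_px=0.0,
                        seed=103)

ff = farneback_flow(mov.frame(0), mov.frame(1), stack.pixel_size_nm, 0.41)
s = summarize_flow(ff, mt.skeleton[0], with_div_curl=False)
true_speed = np.hypot(*mt.flow_um_s[0][:, 128, 128])
print(f"imposed speed {true_speed:.3f} µm/s; "
      f"measured scalar mean {s.scalar_mean_um_s:.3f} µm/s")
print(f"flow coherence {s.coherence:.3f} "
      "(1 = fully directed, as expected for bulk translation)")

det = persistent_nodes(mov, sigma_px=2.5, threshold=0.4)
print(f"\n{len(det)} persistent nodes detected; true anchors:")
for ay, ax in mt.anchor_px:
    d = np.hypot(det["y"] - ay, det["x"] - ax)
    print(f"  anchor ({ay:6.1f}, {ax:6.1f}) -> nearest detection "
          f"{d.min():.1f} px away")
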