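"""Segment the tubule network and validate against ground truth.

Phase-congruency (Feature-Type) enhancement makes segmentation
intensity-independent: a 15 nm tubule is ~16x dimmer than a 60 nm one,
yet both are recovered.  Precision-recall uses one-to-one matching
within half the minimum tubule FWHM (2.5 px).
"""

from erquant.evalstats import precision_recall
from erquant.phasecong import phase_congruency_ft
from erquant.preprocess import build_mask, guided_filter
from erquant.segment import hysteresis_skeleton
from erquant.synth import generate_network_scene

stack, truth = generate_network_scene(n_polygons=30, cisterna_fraction=0.0,
                                      noise_sd=0.0083,
                                      radius_range_nm=(15.0, 60.0), seed=1)
frame = guided_filter(stack.data[0, 0], radius_px=2)
mask = build_mask(frame, stack.pixel_size_nm, n_partitions=2,
                  shrink=0.7, erode_px=4)
ft = phase_congruency_ft(frame)
skeleton = hysteresis_skeleton(ft, lo=0.3, hi=0.5, hmin=0.05)

result = precision_recall(skeleton.pixels & mask.region,
                          truth.skeleton[0] & mask.region,
                          tolerance_px=2.5)
print(f"analysis mask: {mask.area_um2:.1f} µm²")
print(f"skeleton pixels: {skeleton.pixels.sum()}")
print(f"precision {result.precision:.3f}  recall {result.recall:.3f}  "
      f"F1 {result.f1:.3f}")
print("An F1 above 0.9 means the automated skeleton overlaps the truth")
print("almost everywhere within half a tubule width.")
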