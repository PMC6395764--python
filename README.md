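# erquant

Quantitative analysis of cortical endoplasmic-reticulum (ER)
architecture and dynamics from multi-channel fluorescence time series.

The cortical ER of plant epidermal cells is a dynamic polygonal network
of membrane tubules (radii 15–60 nm, well below the ~140 nm lateral
resolution of a confocal microscope) and flattened sheet-like cisternae,
anchored at ER–plasma-membrane contact sites and swept by cytoplasmic
streaming.  `erquant` extracts this network from image stacks and
quantifies, per movie:

* **morphology** — tubule lengths and sub-resolution widths, bulges and
  constrictions along tubules, cisterna and polygon shape metrics,
  GLCM texture of cisternal sub-structure;
* **topology** — an attributed network graph (junctions, free ends,
  puncta, cisterna nodes; edges with length/width/intensity vectors),
  branch angles, node strength;
* **dynamics** — dense optical flow (speed, direction, coherence,
  divergence, curl) and persistency maps of static tubules, cisternae
  and anchor nodes;
* **statistics** — variance-stabilising transforms, MANOVA (Pillai's
  trace, Roy's largest root), canonical discriminant scores, and
  per-metric ANOVA with Tukey HSD comparisons against a control group.

A synthetic-scene generator (`erquant.synth`) renders Voronoi-derived
tubule networks with known sub-resolution radii, cisternae, psf blur,
noise, bulk motion and immobile anchors, so the entire pipeline is
testable with full ground truth and no microscope data.

## The core measurements

**Intensity-independent segmentation.** Tubules are enhanced by phase
congruency over a log-Gabor filter bank (3–5 scales, 4–6 orientations).
The *Feature-Type* statistic — the local weighted mean phase angle
φ = atan2(ΣE, |ΣO|), mapped to [0, 1] — is ≈1 on bright ridges and 0.5
on step edges regardless of local contrast, so dim and bright tubules
segment alike.  Hysteresis thresholding (0.3/0.5) with h-minima valley
suppression (0.05) and Zhang–Suen thinning yields a single-pixel
skeleton.

**Sub-resolution width calibration.** The FWHM of a tubule saturates at
the psf, but its integrated brightness scales with cross-sectional
area.  With sheet reference intensity *I*<sub>s</sub>, sheet thickness
*T*<sub>s</sub> = 40 nm and lateral psf extent psf<sub>xy</sub> = 140 nm,
the tubule radius is

&nbsp;&nbsp;&nbsp;&nbsp;*r*<sub>t</sub> = √((*I*<sub>t</sub>/*I*<sub>s</sub>) · psf<sub>xy</sub> *T*<sub>s</sub> / 4)

where *I*<sub>t</sub> is the psf-footprint mean intensity recovered
from the area under the per-pixel granulometry (opening-scale) curve.

**Flow coherence.**  Coherence = |vector-mean velocity| / scalar-mean
speed ∈ [0, 1]: 1 for fully directed flow, 0 for no net movement.

## Worked example

```sh
python examples/02_segment_and_validate.py
```

```
analysis mask: 12.5 µm²
skeleton pixels: 1180
precision 0.944  recall 0.901  F1 0.922
```

The synthetic scene contains tubules with radii from 15 nm (about 16×
dimmer than a 60 nm tubule) at a signal-to-noise ratio of 5 for the
faintest; an F1 of 0.92 against the known skeleton, with a tolerance of
half the minimum tubule FWHM, means the intensity-independent
segmentation recovers nearly the whole network.  And:

```sh
python examples/03_subresolution_width.py
```

```
true radius  15.0 nm -> FWHM  150.0 nm (psf-saturated), calibrated radius  15.0 nm
true radius  30.0 nm -> FWHM  150.0 nm (psf-saturated), calibrated radius  30.0 nm
true radius  60.0 nm -> FWHM  150.0 nm (psf-saturated), calibrated radius  60.0 nm
```

Every rendered tubule measures ~150 nm across by FWHM — the psf limit —
while the brightness-calibrated estimator recovers the true radii.
The other examples cover graph extraction (`04`), optical flow and
anchor persistency (`05`) and group statistics (`06`).

A thin CLI wraps the same library calls:

```sh
erquant simulate --polygons 30 --frames 5 --seed 1 --out scene/
erquant run scene/movie.tif --pixel-size-nm 25 --out results/
erquant batch --groups groups.csv --control GFP-HDEL --out results/
```

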