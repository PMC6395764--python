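# Methods

This note documents the models, parameter choices and numerical
conventions behind `erquant`, and what the synthetic fixtures do and do
not establish about real data.

## Image model and preprocessing

Input is a calibrated `(t, channel, y, x)` stack with physical pixel
size (20–80 nm) and frame interval (default 0.41 s).  Coordinates are
0-based `(row, col) = (y, x)` with the origin top-left, everywhere
including CSV output; physical positions are `pixel × pixel_size / 1000`
µm.

Processing is standardised by linear upsampling so the thinnest tubule
(FWHM_min, measured by the user on transects) spans ~5 px; the factor
is `ceil(5/FWHM_min × 2)/2` in half-integer steps and divides the pixel
size.  Background is the mean of a user ROI, subtracted and clamped at
zero (later stages assume non-negative intensity).  Smoothing uses a
guided filter with the image as its own guide, kernel = FWHM_min,
regularisation ε = (0.01 × intensity range)² — strong edges
(variance ≫ ε) pass through, flat regions are averaged.

The analysis mask takes the lowest threshold of a 2–4-class multi-Otsu
partition (multi-level partitioning keeps dim ER around very bright
inclusions such as fusiform bodies), fills internal holes, fits the
outer boundary as a contraction of the convex hull (shrink ∈ [0, 1],
1 = full hull, implemented as the hull intersected with a
distance-to-foreground band), and erodes by 4–6 px to drop out-of-focus
margins.  `Mask.region` is the filled boundary interior — this is the
area used for density metrics and the domain for polygon segmentation —
while the dark enclosed holes are carried separately in `Mask.holes`.

## Tubule enhancement and segmentation

Feature-Type is the local weighted mean phase angle of a log-Gabor
bank: min wavelength 3 px, scale multiplier 2.1, 4 scales, 6
orientations, angular σ/Δθ = 1.2.  Per pixel,
φ = atan2(Σ even, |Σ odd|) ∈ [−π/2, π/2], mapped as (φ + π/2)/π so
bright ridges → ~1, step edges → 0.5, dark ridges → ~0.  Because
amplitude cancels in the ratio, the statistic is invariant to linear
intensity rescaling.  Pixels are gated by total filter amplitude
against a Rayleigh-model noise estimate (from the smallest-scale
response median, scaled by `noise_k` = 2) with a floor of 4% of the
per-orientation amplitude maximum.  The floor sits below the ~6%
relative amplitude of the faintest tubule the generator produces
(radius ratio 15/60 squared) but above the far-field halo of the
largest-scale filters, and — being relative — preserves intensity
invariance.

Segmentation: an h-minimum transform of depth 0.05 identifies local
intensity minima, which are set to zero — enclosed shallow valleys
between closely appressed tubules would otherwise be flooded by the
hysteresis fill and merge distinct tubules.  (Valleys open to the
background at both ends are not regional minima and are not suppressed;
deeper valleys fall below the lower threshold on their own.)
Hysteresis keeps pixels ≥ 0.3 that 8-connect to a pixel ≥ 0.5; the
binary image is thinned with the Zhang–Suen algorithm, plus a
connectivity-preserving pass that removes the occasional residual 2×2
block.

Cisternae: grey-level opening with a disc of diameter FWHM_max removes
everything tubule-sized; Otsu on the opened image seeds regions, each
refined by a morphological Chan–Vese active contour (50 iterations,
smoothing 1) that settles the boundary onto the intensity profile.
Regions below 0.3 µm² are returned as punctum candidates (they become
network nodes, not cisternae).  Polygonal regions are the 4-connected
components of `mask − skeleton − cisternae` that do not touch the mask
boundary; components under 4 px are raster pockets at junctions (far
below the psf area) and are dropped.

Shape metrics use this package's conventions, stated here because no
universal definition exists: perimeter is the sub-pixel marching-squares
contour length after a 5-point circular moving average (so a disc's
circularity → 1); solidity = area/convex area; elongation = 1 −
minor/major axis; circularity = 4π·area/perimeter²; roughness =
perimeter/convex-hull perimeter.  Single-pixel regions get NaN axes.

## Width estimation and psf calibration

Three estimators per skeleton pixel:

* **FWHM** — twice the Euclidean distance at which intensity first
  falls below half the skeleton-pixel value.  Quantised upward by up
  to 1 px per side (distance to the first sub-half *pixel*), and
  saturates at the psf for sub-resolution tubules.
* **Granulometry gradient** — openings with discs of radius 0..FWHM_max
  build an intensity-vs-scale curve (forced monotone by a running
  minimum, since discrete discs are not perfectly nested); the scale of
  the steepest drop is the width, ties breaking toward the smaller
  scale.  Integer-constrained, so coarse.  Closing-based curves are
  available behind a flag; opening is the default.
* **Calibrated radius** — the area under the granulometry curve above
  its final-scale plateau approximates half the integrated
  cross-sectional line brightness L (the curve reproduces the profile
  normal to the axis).  Expressed as the mean intensity over a
  psf-diameter disc footprint, I_t = 4L/(π psf_xy), and referenced to
  the sheet intensity I_s, the radius is
  r_t = √((I_t/I_s) psf_xy T_s/4) with psf_xy = 140 nm and
  T_s = 40 nm.  I_s is measured as the mean over cisterna interiors
  eroded by 2 px when cisternae exist, else taken from configuration
  (default 0.35 of maximum).  The model assumes a uniformly
  luminal-filled tubule, linear intensity, and full containment in the
  psf; intensity rescaling cancels between I_t and I_s.  The mean
  cortical ER width from electron-microscopy reconstructions
  (40.51 nm) is carried in the calibration object as context for
  judging outputs.

## Graph representation

Skeleton pixels with ≥3 neighbours (8-connected) are junction pixels,
clustered into one node at their centroid; elongated junction clusters
(diameter > 3 px — a short tubule whose pixels all sit at junction
density) are split into two nodes joined by an internal edge so the
faces on either side stay distinct.  Chains of degree-2 pixels are
traced into edges with ordered pixel paths; length is the sum of 1/√2
steps plus the closing steps to each node, × pixel size.  Directly
touching clusters get one contact edge per pair.  Cycles whose
rasterised interior is below the 4-px polygon minimum are raster
artifacts and the redundant arm is removed, keeping graph cycles in
one-to-one correspondence with segmented polygons (Euler:
faces = E − V + C).  Remaining parallel edges and self-loops are split
by degree-2 "resolver" nodes (a self-loop needs two) which are excluded
from junction statistics.  Free-end spurs shorter than FWHM_min are
pruned by default.

Edge widths: the centre-weighted width averages the calibrated width
over path pixels farther from each endpoint than the maximum initial
width of the tubules meeting that node (junction signal excluded);
edges entirely inside the exclusion fall back to the unweighted mean,
flagged.  Node properties: branch angles are the circular gaps between
chords from the node to each edge's half-arclength point (sub-pixel
interpolated); circular mean direction and resultant length follow the
standard conventions; strength is the sum of incident centre widths.
Cisternae enter as one node at the intensity-weighted centroid,
connected to every node within 2 px of their boundary by edges flagged
`is_cisterna_internal` (width = global mean centre width, Euclidean
length); these count for topology but are excluded from tubule
statistics.  Puncta snap to a node within FWHM_min, else insert as
isolated punctum nodes.

## Profiles, texture, dynamics, persistency

**Tubule profiles.** Intensity is integrated normal to the local axis
(tangent from ±2 path pixels; half-pixel sampling over ±FWHM_max/2),
node zones excluded.  Peaks need height ≥ 5% and prominence ≥ 3% of the
trace maximum; troughs are peaks of the inverted trace; same-kind runs
reduce to their extreme member so events alternate.  Both the tubule
width at the event and the event's own extent are available (the
printed "width" of an event is ambiguous; both are emitted).  Traces
are not smoothed by default (the thresholds already reject noise); a
3-point moving mean is available behind a flag.  Two-channel traces
give per-event ratios and a Pearson correlation (negative = anti-phase
localisation).  Boundary profiles average intensity in signed integer
EDT bins (−1 = first interior ring, 0 = first exterior ring).

**Texture.** The GLCM accumulates intensity-bin pairs at offsets NW, N,
NE, E (distance = minimum tubule radius) plus symmetric counterparts,
over 32 fixed bins spanning a fixed intensity range shared across a
study (bit-depth range for real data) — per-region ranges would break
cross-treatment comparability.  Pairs with a member outside the region
are dropped.  Metrics: contrast Σ|i−j|²p normalised by (n−1)²,
correlation Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ), energy Σp², homogeneity
Σp/(1+|i−j|).  On a perfectly uniform region the formulas give contrast
0, homogeneity 1, energy 1 and an undefined correlation (σ = 0, flagged
NaN); descriptions of an idealised sheet as "zero energy, correlation
1" conflict with the formulas and the formulas are followed.  Both
per-cisterna-mean and pooled (pair-count-weighted) aggregation are
provided.

**Optical flow.** Farnebäck polynomial-expansion flow is implemented
in-package: quadratic expansion with Gaussian applicability
(neighbourhood 5 px, σ 1.1), displacement solved from the coefficient
shift aggregated over a 15-px window, 3 iterations per level of a
3-level pyramid.  The px/frame field is box-averaged over 15 px and
then converted to µm/s (order fixed for bit-reproducibility; the
alternative order is mathematically identical).  Alternative flow
estimators can be plugged in as a callable.  Summaries per element:
scalar mean |v|, |vector mean|, max, coherence = vector/scalar (0 when
the scalar mean is 0), circular direction statistics.  Divergence
∂vx/∂x + ∂vy/∂y and curl ∂vy/∂x − ∂vx/∂y use central differences in
s⁻¹; border pixels are NaN.  Speed distributions are fitted as
Gaussians in log space; `back_transformed_mean` is exp(µ) and the
arithmetic lognormal mean exp(µ + σ²/2) is also reported; zeros are
excluded and counted.

**Persistency.** Intensity persistency follows the
difference-over-a-lag approach: |I(t) − I(t+lag)| masked by the AND of
Otsu segmentations at both ends, normalised to the OR occupancy.
Structure persistency dilates skeletons and cisterna masks by
FWHM_min/2 and either sums occupancy over the window (graded) or ANDs
the endpoints (binary; a pixel vacated between occupied endpoints still
scores persistent — a documented limitation of the endpoint
definition).  The default lag is 12 frames (~5 s at 0.41 s); there is
no agreed persistency duration, so it is configurable, and all outputs
are in seconds (frames × frame interval).  Persistent nodes come from a
temporal median over the whole time course (an optional rolling window
exists but is off), Gaussian smoothing with σ = FWHM_min/2, min–max
normalisation and local maxima above a 0.3–0.5 threshold (default 0.4).

## Statistics

Skeleton validation uses precision/recall with greedy one-to-one
matching within half FWHM_min (a truth pixel cannot absorb several
automated pixels); F1 = 2PR/(P+R) equals the Dice coefficient of the
matched sets.  Ground truth is thinned and masked like the automated
skeleton with cisternae excluded.

Group comparison: [0, 1]-bounded metrics are arcsin-√ transformed;
wide-range metrics use log, √ or logit (logit inputs clamped to
[0.025, 0.975]); transforms are recorded and invertible.  The MANOVA
(Pillai's trace and Roy's largest root with F approximations) is
computed via statsmodels; canonical discriminant scores come from the
generalised eigendecomposition of the between/within scatter.  Tukey
HSD uses the Tukey–Kramer studentized-range statistic implemented
vectorised in-package (p-values and critical values from the
studentized-range distribution; verified against an independent
implementation in the tests), with flags at 0.05/0.01/0.001 against
the control.  Sphericity is not corrected (Mauchly's test may fail;
with the effect sizes this pipeline is used at, conclusions are
insensitive), and the non-normality of persistency distributions is
warned about rather than silently handled.  The metric subset entering
the MANOVA is configurable; each metric summarises a movie by its mean
by default.

## Synthetic scenes: what they emulate, and what they do not

Scenes are Voronoi tessellations of 20–80 nm/px fields (default 25 nm,
256²): interior ridges become tubules with radii drawn uniformly from
15–60 nm, a chosen fraction of closed faces become uniform sheets, and
anchors are bright static puncta (peak 0.5 vs 0.35 for sheets,
matching the bright persistent puncta associated with immobile scaffold
sites).  Intensity is thickness-equivalent signal: a sheet of thickness
T_s renders at I_s before blur, and a tubule deposits line mass
π r²/pixel × I_s/T_s — integrated brightness proportional to
cross-sectional area, so the width calibration is exactly recoverable
by construction.  The psf is a Gaussian of 140 nm FWHM; the tubule's
own cross-sectional extent is folded into it (exact for integrated
brightness, a few percent narrow in FWHM for the thickest tubes).
Noise is additive Gaussian with optional Poisson shot noise; the
default SNR convention is worst-case (noise SD = faintest tubule peak
/ SNR).  Edges shorter than 4 px (below the resolvable scale) are
contracted to a point, keeping the geometric topology consistent with
what the raster can represent.  Animation displaces network vertices
by a per-frame bulk translation plus rigid jitter; vertices within a
pin radius of an anchor stay put (their tubules stretch), and the
truth flow equals the imposed displacement over the frame interval,
zeroed at anchors.  Total geometric tubule length is invariant under
pure translation.

Problem sizes used throughout the tests and the acceptance script —
256² single frames, movies of 3–30 frames, 20-scene validation sets,
10⁴-replicate null simulations — were chosen so the whole suite runs
on a laptop-class single core in minutes.

What passing these fixtures does **not** show: robustness to focus
drift and the curved cell cortex, photobleaching, non-uniform
background, fluorophore maturation, genuinely curved tubules (edges are
straight segments), cisternal sub-structure texture (synthetic sheets
are uniform), or biological motion beyond rigid translation + jitter
(no remodelling, sliding, or tubule growth).  Reported real-data
quantities such as published speed means or segmentation scores depend
on the original image sets and are outside what this package's
fixtures can reproduce.

## Known limitations

* FWHM widths are quantised (integer EDT radii) and psf-saturated;
  they are reported for comparability, not accuracy.
* The h-minimum suppression only separates valleys that form enclosed
  basins; two appressed tubules whose valley drains to background at
  both ends will still merge if the valley stays above the lower
  hysteresis threshold.
* Raster near-misses between tubules closer than a pixel can bridge
  and close an extra face relative to the generating geometry (the
  graph and the polygon segmentation stay consistent with each other).
* The endpoint-difference persistency mode cannot see interruptions
  between its endpoints.
* MANOVA assumes no missing cells; movies with absent structures (e.g.
  no cisternae) produce NaN metrics that must be dropped or imputed
  before comparison (`batch` drops all-NaN columns).
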