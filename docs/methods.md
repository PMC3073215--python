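# Methods

## Problem and pipeline

Two-probe FISH slides for HER2 status carry three signals: a DAPI nuclear
counterstain (blue channel), HER2 probe dots (red/orange) and CEP17
centromere-17 probe dots (green). Scoring follows the clinical convention:
count red and green dots inside each nucleus, form the per-nucleus ratio
red/green, average the ratio over up to 60 nuclei, and call the case
**amplified** when the mean exceeds 2.2, **non-amplified** below 1.8, and
**equivocal** in the closed band [1.8, 2.2]. The literature is not fully
consistent here — a single cutoff of 2.0 is also quoted — but the 1.8/2.2
band scheme subsumes it and is what this package implements, with strict
inequalities on both sides of the band (so 2.22 classifies as amplified and
2.2 exactly as equivocal).

The pipeline per image is: channel split and normalization to [0, 1] →
nucleus segmentation from blue → DAPI quality control → dot detection in
red and green with one or both engines → per-nucleus scoring. Nuclei from
several images of one case are pooled until the cell budget is reached. In
`both` mode the two detection engines share one segmentation, so their case
scores form a paired comparison of the detectors alone.

## Nucleus segmentation

Median smoothing (disk radius 2 px) → Otsu threshold → hole filling →
watershed split → shape/size gating → relabeling 1..K in raster order of
centroids. All choices are deterministic; two runs on the same input are
bit-identical.

Watershed markers are the h-maxima of the Euclidean distance transform
with depth `watershed_h` (default 0.1) expressed as a fraction of the
maximum distance. The distance map is Gaussian-smoothed (σ = 1.5 px)
before marker extraction: a ragged threshold boundary superimposes small
humps on the distance ridge of an elongated nucleus, and without smoothing
those humps split single nuclei. Genuinely fused nuclei have saddle depths
of tens of percent of the peak distance and are unaffected by either the
smoothing or the default h.

Objects are kept when area ∈ [500, 50 000] px, solidity ≥ 0.85,
eccentricity ≤ 0.95, and the object does not touch the image border (a
clipped nucleus cannot guarantee complete dot content — standard
FISH-scoring practice). The gates were set on the synthetic fixtures and
are all configurable.

`qc_dapi` flags a slide as `no_dapi_suspected` when the segmented nuclear
area fraction is below 1% or the 99th-percentile blue intensity is below
0.05. A flagged slide is never silently scored: with no nuclei there are
no in-nucleus dots, the case raises an explicit unscorable-case error
carrying the QC context, and the flag always appears in the report. This
guards against the real failure mode in which an image captured without
DAPI lets probe dots be counted outside any nucleus.

## Morphology (MM) engine

With a flat disk structuring element (SE) of radius 5 px, the top-hat
`TH = I − opening(I)` extracts bright details smaller than the SE and the
bottom-hat `BH = closing(I) − I` extracts dark ones; both also equalize
uneven background. The combined enhancement

    E = clip(I + TH − BH, 0, 1)

pushes small bright details toward white and surrounding texture toward
black; clipping makes the saturation explicit. All morphological operators
use reflective (symmetric) border padding — the tests pin this down by
exact comparison with brute-force sliding min/max windows.

Dots are the connected components of `E` above a per-nucleus threshold
(nuclei differ in background level, so a global threshold is wrong). The
default threshold is Otsu computed on the enhanced values inside the
nucleus mask, floored at mean + 3σ of those values: plain Otsu bisects the
noise whenever a nucleus contains no dot in a channel, and the floor makes
the no-dot case return zero detections instead of dozens of specks. A
pure mean + kσ mode is available. Components must have 4 ≤ area ≤ π·r²_SE
pixels; a "dot" larger than the SE contradicts the enhancement premise,
and at the study noise level isolated noise excursions form clusters of at
most 2–3 pixels while the smallest true dot component is ~8 px, so the
4 px floor separates them with margin.

## Inverse multifractal (IMF) engine

The local (Hölder) exponent α(i, j) is the least-squares slope of
log μ_ε(i, j) versus log ε, where μ_ε is the sum of intensities over the
centered (2k+1)×(2k+1) window, ε = 2k+1, k ∈ {0, 1, 2, 3} (widths 1, 3, 5,
7 — dots are only a few pixels across, larger windows wash them out). The
measure is floored at 10⁻¹² so the logarithm is always finite. A smooth
region has μ ∝ ε² and hence α = 2 (the embedding dimension, exact to
machine precision on constant images); a small bright dot concentrates
mass so its μ is nearly scale-constant and α drops below 2. `max` and
`min` measures are provided for experimentation (constant images then give
α = 0).

The spectrum f(α) is estimated by the histogram method: the observed α
range is split into 100 equal bins; for each bin and each dyadic box size
δ ∈ {1, 2, 4, 8, 16}, N_δ counts the δ×δ grid boxes containing at least
one pixel of the bin; f is the least-squares slope of log N_δ versus
log(1/δ), and empty bins get f = 0 by convention. A full-support bin
yields f = 2, an isolated-pixel bin f ≈ 0. The spectrum is computed over
the whole image, not per nucleus: rarity is meant globally.

Inverse selection keeps pixels whose α lies in the configured tail of the
α distribution **and** whose f value is at most `f_max` (default 1.0):
dots are locally irregular (extreme α) and globally rare (low f). Which
tail is "dot-like" depends on the measure convention; descriptions of
spikes as "high α" exist in the literature, but under the sum (capacity)
measure used here bright dots sit *below* the background value 2, so the
default tail is `low` and the `high` tail remains available in
configuration.

The tail percentile default is 1.0. This selector cutoff is a genuine free
parameter, calibrated on the synthetic fixtures: the selection must cover
the dot cores (dot pixels are ~0.3–0.5% of a typical frame) but not reach
into the bulk of the background-noise α distribution. Percentiles of 5 or
more select an order of magnitude more pixels than dots can account for,
and the surplus noise pixels defeat every f cutoff because rare noise bins
are themselves low-dimensional — their clusters then survive as false
dots. Percentiles ≤ 2 leave exact per-nucleus count recovery at 100% on
the benchmark conditions; 1.0 sits in the middle of that plateau.
Selected pixels are restricted to nucleus masks, connected components are
extracted, and the same area gates as the MM engine apply.

## Scoring rules

Dots are assigned to the nucleus whose label lies under their rounded
centroid. A nucleus with no green (CEP17) signal has an undefined ratio
and is excluded from the average (at least one centromere-17 copy per
nucleus is biologically expected; its absence indicates a detection
failure, not biology). The case mean is the mean of per-nucleus ratios —
not the ratio of summed counts, which differs under heterogeneity;
ratio-of-sums is available as a config alternative. When fewer scorable
nuclei than the 60-cell budget are available, all are used and the
shortfall is recorded as a QC note.

Merged red signals are a known limitation: two probes closer than about
the dot width render as one component and are counted once. A naive
area-based estimator (`est_count = max(1, round(area / reference))`, with
the reference the median green single-dot area of the case) is provided
but disabled by default. On MM components, whose areas are geometric, it
recovers roughly a factor-2 count for merged pairs and visibly reduces the
undercount bias; on IMF components it is nearly a no-op, because the
α-depression core of a merged pair is only ~1.4× a single-dot core and
rounds back to 1. Proper separation of merged dots needs dedicated
post-processing and is out of scope.

## Synthetic benchmark data

The generator renders, deterministically per seed: elliptical nuclei
(semi-major axis 20–30 px, axis ratio 1–1.5 to exercise the eccentricity
gate, fill 0.55 with mild multiplicative texture) placed without overlap
and away from borders; isotropic Gaussian dots (σ = 1.5 px, peak 0.8,
truncated at 4σ, additive with a single final clip to [0, 1]) placed
inside nuclei with same-channel center separation ≥ 6σ; uniform red/green
background 0.1; additive Gaussian noise σ = 0.02. These sizes and levels
describe a typical well-acquired slide under the standard probe kit: dots
a few pixels wide, well above background, moderate camera noise. Two
failure modes are reproducible: `no_dapi` (blue is pure noise) and
`overlap_fraction` (the given share of red dots is rendered 1.5σ from
another red dot, which merges their profiles). Images are quantized to
16-bit by default.

What the generator does **not** emulate: optical PSF and chromatic
aberration, photobleaching, clustered or poorly stained nuclei,
autofluorescent debris, z-stack defocus, or dot brightness variation.
Passing the synthetic benchmarks therefore demonstrates the internal
correctness and calibration of the pipeline under clean acquisition
conditions, not clinical-grade accuracy on real slides.

## Problem sizes and numerics

The benchmark case is a 700×700 frame with 20 nuclei; recovery statistics
aggregate five such cases (100 nuclei) per condition. Least-squares slopes
(α and f) use the closed-form centered formula; α-bin edges span the
observed range, with a degenerate (constant-α) image widened to a single
occupied bin. Box sizes need not divide the image; partial edge boxes
count as boxes. Ties in nucleus relabeling are broken by raster order of
centroids, making reports byte-stable. All randomness flows through a
single seeded generator; rendered images, label maps and report files are
bit-identical across reruns.

## Known limitations

* Calibration (SE radius, area gates, α percentile, f ceiling) targets the
  synthetic dot scale; slides with markedly different magnification need
  re-configuration.
* Nuclei touching the border are discarded, biasing against dense fields.
* The detectors count merged signals as one (see the estimator caveat
  above).
* The classifier consumes whatever mean ratio it is given; with fewer than
  60 scorable nuclei the call rests on a smaller sample and carries only a
  QC note, not a wider decision band.
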