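# Methods

## Encapsulation model

Random encapsulation of a dilute, well-mixed cell suspension into droplets
of volume V (pL) at cell density c (cells/mL) yields per-droplet cell
counts K ~ Poisson(λ) with λ = c·V·10⁻⁹.  The package keeps the three
quantities linked in `EncapsulationModel` (consistency enforced to 1e-9
relative) and computes droplet volume from diameter as V = (π/6)d³ with
1 pL = 10³ µm³, so a 55 µm droplet evaluates to 87.1 pL; the volume is
always derived from geometry rather than hard-coded, since quoted nominal
volumes are roundings of the same sphere.

Occupancy is estimated from imaging data via the empty fraction only:
λ̂ = −ln(f_empty) is the Poisson MLE when observations are reduced to
empty/non-empty, which is all the growth threshold can distinguish.  The
estimator deliberately reports an *effective* λ: non-viable cells, clumping
and aggregation all inflate the observed empty fraction relative to the
nominal dilution target, and no correction factor is applied because none
of these mechanisms is identified by the data.  "More than one cell" is
interpreted as the tail P(K ≥ 2), not P(K = 2).

## Synthetic scene generator

The generator emulates the statistical structure that the analysis
assumes, with ground truth attached so that detection and quantification
can be scored against known answers.

**Conditions (defaults).** Mean diameter 55 µm with normal variation at
CV 5% (truncated at ±4 SD, strictly positive); occupancy λ = 0.11; pixel
scale 0.5 µm/px (a 55 µm droplet spans ~110 px; configurable — many tests
use 1.0 µm/px to keep images small while radii stay above 20 px).
Coordinates are (row, col), 0-based, origin top-left, half-open bounds,
everywhere in the package.

**Growth model.** Occupied droplets follow a lagged logistic trajectory:
b(t) = b₀ for t ≤ lag, then the solution of db/dt = r·b·(1 − b/cap) with
b(lag) = b₀, i.e. b(t) = cap / (1 + ((cap − b₀)/b₀)·e^(−r(t−lag))).  b₀ is
`cell_count × seed_fraction` with seed_fraction 10⁻³ (one founding cell is
roughly one-thousandth of the cross-sectional area of an 87 pL droplet).
Each droplet draws its class once — fast with probability `fast_fraction`
(default 0.5) — and the two classes default to lag 2 h / rate 2.5 h⁻¹ /
capacity 0.60 (fast; saturating within ~6 h of inoculation) and lag 4 h /
rate 0.10 h⁻¹ / capacity 0.25 (slow; accumulating modest biomass over
days), chosen to reproduce the observed pattern of rapid aerobic
saturation versus slow growers that need days.  Per-droplet multiplicative
log-normal jitter (σ = 0.2) on rate and capacity spreads each mode into a
distribution rather than a spike.  At post-lag time points the non-empty
growth values are therefore bimodal, with upper-mode mass equal to the
fast fraction — the "bivariate" growth pattern of mixed communities.

**Rendering.** Background 0.45, droplet interior 0.58, rim 0.12 (fractions
of full scale; rim width 2.5 px), biomass 0.18 ± texture; additive Gaussian
noise with SD 0.012 is applied last and the image quantized to 8 or 16
bits.  These intensities were chosen so that the Canny stage responds to
rims and biomass (contrast ≈ 0.3–0.4) but not to background noise (an
order of magnitude smaller); all are exposed in `OpticsParams`.  Biomass is
painted by ranking interior pixels with a style-specific priority (blob
distance, clump centers, or a random-walk filament polyline) and taking
exactly the target pixel count, so rendered coverage matches the
ground-truth fraction up to rounding; a fraction (15%) of painted pixels is
reverted to interior brightness in ~2–3 px granules, giving dense biomass
the internal edges that real cell clumps show — without internal texture an
edge-based measurement could only ever see a blob's outline.  Droplet
placement is rejection-sampled to keep interiors disjoint and fully inside
the image; empty droplets carry exactly zero biomass.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: uneven illumination and vignetting,
focus drift and partial-focus droplets, droplet shrinkage or coalescence,
motile cells, overlapping or touching droplets (emulsions at high packing),
debris and dust, and double counting of droplets across overlapping stage
positions.  Detection and measurement accuracies reported by the test
suite are upper bounds for well-behaved images.

## Droplet detection

Localization is not part of the published measurement chain and is the
largest inferred component: droplets are found with a circular Hough
transform over a Canny edge map (same blur/edge operators as the biomass
stage, σ = 1.5 px), searching radii in a configurable range (default: the
expected radius ± 25%).  The accumulator is perimeter-normalized, so the
`sensitivity` threshold (default 0.35) is the minimum fraction of a
circle's perimeter supported by edges — blank noise images yield nothing.
Candidate circles are suppressed if they overlap a kept circle by more
than 10% of the smaller area; the higher accumulator score wins, with ties
broken by smaller row then smaller col.  Each kept circle's radius is then
refined to sub-pixel precision as the parabolic-interpolated minimum of
the radial mean-intensity profile (the rim centerline), which removes the
integer-radius quantization and the inner/outer-rim-edge ambiguity of the
raw Hough estimate.

Droplets whose circle crosses the image border are flagged `border` and
excluded from measurement rather than measured partially, because area
fractions on clipped circles are biased.  Monodispersity statistics (mean,
SD, CV of diameters in µm) use non-excluded ROIs only, with the sample
(n−1) SD — the same denominator used everywhere SD appears in the package.

## Growth quantification

The per-droplet measurement is the operator chain Gaussian blur (σ = 1.5
px) → Canny edge detection → morphological closing (disk, radius 2 px),
then restriction to the droplet interior; the growth value is
foreground / interior pixels, exactly, and lies in [0, 1].

Numerical choices:

* **Rim margin.** The droplet's own dark rim produces strong edges that are
  not biomass, so the interior is the detected disk eroded by 3 px (at
  0.5 µm/px).  Without this, empty droplets score well above zero.  The
  interior (rim-eroded) area is also the denominator, so a completely full
  droplet reaches 1.0.
* **Adaptive Canny thresholds.** Defaults are derived per image (not per
  droplet crop) from the Sobel gradient magnitude of the blurred frame —
  the same operator and scaling Canny applies internally: low = median +
  5 × 1.4826 × MAD, high = 1.6 × low.  Computing them per crop would let a
  biomass-rich droplet inflate its own threshold and erase its own signal.
  Fixed values can be supplied instead and all effective values are logged.
* **Bit depth.** Images are normalized to [0, 1] before filtering; 8- and
  16-bit encodings of the same content give identical masks.
* **Proxy, not estimator.** Edge-plus-closing coverage systematically
  under-measures large solid regions (closing with a radius-2 disk fills
  gaps and holes only up to ~4–5 px), so the growth value is a monotone
  proxy of biomass, not an unbiased area estimate; the test suite asserts
  rank agreement (Spearman ρ ≥ 0.8 against ground truth), never absolute
  recovery, except for small disks (~3–4 px radius) which the closing
  genuinely fills.

## Growth scoring

The day-0 population defines the threshold T = mean + 2·SD over *strictly
positive* day-0 growth values (sample SD; a single positive value falls
back to SD = 0; an all-zero day 0 is an error instructing the user to
supply a floor).  Classification is strict: g > T counts as grown; a value
exactly at T does not, since T is a noise ceiling.  The normalized growth
score is G_A·N/G_A-Max.  N = 0 yields score 0 — "no droplets grew" is a
meaningful zero — with G_A and G_A-Max reported as NaN.

The published formula does not scope G_A-Max.  The default here is
**series-global**: the maximum above-threshold growth value across the
whole compared time series, consistent with normalizing a growth curve to
its final time point, so a monotone series peaks at its last time point
and scores are comparable across time points.  A per-timepoint scope is
available by configuration; the two agree at the time point holding the
global maximum.  Per-droplet normalized values (value / G_A-Max) are also
provided for violin-style distribution plots — the scalar score and the
per-droplet distribution are two uses of the same ingredients.

Distribution comparisons use the two-sided Mann-Whitney U test: exact
enumeration when both samples are ≤ 20 and tie-free, otherwise a normal
approximation with tie-corrected variance, a 0.5 continuity correction and
an Edgeworth kurtosis term.  The exact null excess kurtosis of U is
γ₂ = −(6/5)(m² + n² + mn + m + n)/(mn(N+1)) (verified against exact
enumeration to machine precision), and adding φ(z)(γ₂/24)(z³ − 3z) keeps
the approximation within ~0.002 of exact enumeration at sizes 5–15, making
the exact/asymptotic switchover seamless.

## Pipeline and I/O

A run is fully described by a serializable `RunConfig` (YAML): inputs or a
synthetic-scene spec, pixel size, detection and quantification overrides,
threshold policy, normalization scope, seed, output directory.  Time
points are hours, from an explicit mapping or from `_t<H>h` / `_d<D>`
filename suffixes (days converted on ingest).  Images are single-channel
8/16-bit TIFF or PNG; multi-channel input is rejected with a conversion
hint.  Outputs are TSV tables (UTF-8, dot decimal, floats at 6 significant
digits), a YAML config snapshot and a timestamped plain-text log recording
every effective parameter, so a published-figure-style analysis is
auditable and a rerun from the persisted config and seed reproduces every
table cell byte-identically.  Each image is processed independently;
droplets appearing in overlapping stage positions are not deduplicated.

## Problem sizes used in tests and the acceptance script

Image-level checks run at 1.0 µm/px on 640² (or smaller) scenes with
radii ~27 px — above the 20 px regime where the detector is specified to
operate — with 12–30 droplets per scene: 20 seeded scenes for the
detection round-trip, ~1,000 detected droplets for CV recovery, and 50
rendered day-0 populations for the threshold false-positive rate.
Statistics-level checks that need large cohorts use ground-truth
trajectories without rendering: 50,000 droplets for λ recovery and 20
replicates of 600 droplets for the two-timepoint Mann-Whitney contrast.

## Known limitations

* The growth value is resolution-dependent: the rim margin, closing radius
  and blur are pixel quantities, so comparisons are only meaningful within
  a series measured at one pixel scale with one parameter set (enforced by
  convention, logged, not checked across runs).
* Day-0 thresholding assumes day-0 positives represent measurement noise
  around unexpanded inocula; pre-grown or aggregated inocula would inflate
  T and depress N.
* The λ estimator conflates non-viability, clumping and detection misses
  into one effective occupancy.
* Overlapping-field deduplication, non-circular (deformed) droplets and
  multi-channel (e.g. fluorescence) measurements are out of scope.
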