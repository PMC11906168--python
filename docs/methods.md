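# Methods

`steppemap` implements pixel-based habitat-type classification of
multitemporal UAV RGB orthomosaics for grassland monitoring: four classes —
steppe (C0), shrubs (C1), forest-steppe (C2), bare/fallow land (C3) — are
discriminated from per-pixel descriptors of the 3-band images, fused over the
acquisition time series, with a random-forest classifier, grouped
cross-validation, feature selection, and dense map inference with decision
confidence.

## Problem setting and assumptions

The target imagery is a series of T co-registered 8-bit RGB orthomosaics at a
ground sampling distance (GSD) around 4 cm, acquired over one growing season
(default: six dates from mid-April to the end of September). At this
resolution individual plants are not resolvable, and an RGB sensor carries
little spectral information; the classes are therefore assumed to be
characterized by (i) image *texture* of the plant mixtures, (ii) local
*morphology* (granularity of bright/dark structures), and (iii) the seasonal
*color trajectory* (phenology). The model is pixel-based: each labeled pixel
is described by statistics of its square spatial neighbourhood, per date, and
the per-date descriptors are concatenated (feature-level temporal fusion).

## Descriptors

All spatial descriptors are computed from the channel-mean grayscale
g = (R+G+B)/3 (channel-neutral wideband luminance; 8-bit values are promoted
to floats before any descriptor math).

**GLCM texture (54 per date).** For each pixel, gray-level co-occurrence
matrices are accumulated over centered square windows of 17, 31 and 61 px
(0.7/1.2/2.4 m at 4 cm GSD) from pixel pairs at L∞ distance 4, 8 and 16 px
respectively, at 45° — offset (−d, +d) in (row, col) — counted symmetrically
(so the sign convention is immaterial; asserted by test). Gray levels are
quantized into 16 bins over the *fixed* range [0, 255]; per-window min–max
rescaling would destroy comparability across windows, and 16 levels keep even
the 61 px window's matrix well populated. Eighteen statistics per window
(energy, entropy, correlation, homogeneity, contrast, cluster shade, cluster
prominence, Haralick correlation, mean, variance, dissimilarity, sum
average/variance/entropy, difference entropy, difference variance, and both
information measures of correlation) follow the Haralick/Conners canon with
natural logarithms and 0·log 0 ≡ 0; level indices are 0-based. On a
zero-variance window the correlation-type statistics are defined as 0. Note
that with symmetric accumulation the "correlation" and "Haralick correlation"
closed forms coincide; both names are kept so the 18-statistic contract and
naming match the conventional feature list. Rasters are reflect-padded by
half the largest window so feature maps stay full-size; a validity mask flags
pixels whose window reached into the padding.

**Morphological profiles (11 per date).** Openings and closings by
reconstruction with a discrete Euclidean disk of radius r = 1…5 px form two
5-level profiles. Only derived quantities are emitted: the 4 + 4 absolute
differences between successive profile levels (structures appearing at each
scale transition), one "characteristic" per profile (the 1-based scale index
of the maximal derivative, 0 where all derivatives are below the flat
threshold; ties break to the smallest scale), and one "classification" value
(1 bright-dominated, 2 dark-dominated, 0 flat; equality counts as flat). The
flat threshold defaults to 1 gray level, preventing noise-driven labels.
Derivatives are taken between successive levels only, never against the
original image (5 levels → 4 derivatives).

**Spectral (9 per date).** R, G, B plus six visible-band indices:
colRG = (R−G)/(R+G+ε), colBG = (B−G)/(B+G+ε), GRratio = G/(R+ε),
BGratio = B/(G+ε), pGluminance = (R+G+B)/3 and
GreenLeaf = (2G−R−B)/(2G+R+B+ε), with ε = 10⁻⁶ guarding zero denominators.
These are the conventional definitions of the respective index families; the
exact variants are configuration, not data.

Fused over T dates the combined descriptor has D = T × (54+11+9) = 444
dimensions for a 6-date series, named `<date>_<feature>` in date-major order.

## Ground-truth sampling and grouped cross-validation

Steppe reference data comes from 1 m × 1 m survey plots of unrecorded
orientation: every pixel whose center falls inside the circle inscribed in
the plot is a sample. The inscribed circle of a 1 m square has radius 0.5 m,
which is the default (`radius_m` is configurable). Shrub and bare-land
references are single GPS points (one pixel each, nearest center, ties to the
smaller index; duplicates dropped); the forest-steppe class is sampled at
equal arc length along a transect polyline, endpoints included (by target
count, default 134, or by spacing). This reproduces the strong class
imbalance characteristic of such campaigns (thousands of steppe pixels vs.
tens–hundreds for the minority classes).

Because samples within one plot are highly correlated, cross-validation is
grouped: each steppe plot is one evaluation unit held out whole, and each
minority class is randomly partitioned into five disjoint subsets acting as
units. Every unit is held out exactly once, a forest is trained on the rest,
and the pooled held-out predictions fill a single 4×4 confusion matrix.

## Classifier, metrics, and model comparison

The classifier is a random forest: default 500 trees, √D features per split,
unlimited depth, no class re-weighting by default (the imbalance bias is part
of the design being emulated; weighting is exposed but off). Vote fractions
of the ensemble (trees grown to purity) are the per-pixel decision
confidence.

From the pooled confusion matrix the package reports overall accuracy,
Cohen's κ with a 95 % CI, and per-class producer's accuracy (recall), user's
accuracy (precision), one-vs-rest binary accuracy and F-measure, plus class
averages (computed from unrounded values). The κ variance uses the full
four-term delta-method form (θ₁–θ₄ of the joint cell proportions and both
marginals); the simplified p_o(1−p_o)/(n(1−p_e)²) approximation understates
the half-width on imbalanced matrices and does not reproduce the benchmark
values. Display rounding is half-up to two decimals. Two models are compared
with a two-sided κ z-test using the sum of the two variances (α = 0.05).

## Feature selection

A two-step, VSURF-style procedure on random-forest importance statistics:

1. *Ranking/threshold*: permutation importance averaged over 20 independent
   forest replicates; each replicate fits on a stratified 70/30 split and
   permutes columns on the held-out 30 % (a fast, nonparametric stand-in for
   per-tree out-of-bag permutation importance — chosen so many-seed
   benchmarks stay tractable on one CPU). The retention threshold is the
   minimum of a regression-tree (piecewise-constant) fit of importance
   standard deviation versus rank: the flat low-sd tail is where pure-noise
   features live.
2. *Interpretation*: nested forests over growing ranked prefixes; keep the
   smallest prefix whose OOB error is within one standard deviation (from 10
   replicate forests at the best size) of the minimum. This step tolerates
   correlated but relevant features.
3. *Prediction*: greedy forward addition in interpretation order; a feature
   enters only if it lowers the OOB error (averaged over two replicate
   forests) by more than the typical OOB fluctuation, estimated from the flat
   tail of the interpretation trajectory or from replicate forests. This
   step removes redundant copies.

The three sets are nested by construction. Selection forests default to 100
trees. Exact numerical replication of the reference R implementation is out
of scope; the semantics (nested sets, OOB-based decisions) are preserved.

## Dense mapping and zone statistics

Map inference is tiled and streaming: only the features the deployed model
uses are computed, per tile, directly from the series. Every descriptor is a
function of the global rasters and the pixel position (texture windows read
from the same reflect-padded raster; morphological reconstruction is
precomputed whole-image per date), so maps are bit-identical for any tile
size. Per-pixel confidence is the winning vote fraction; pixels below the
threshold (default 0.6) form the low-confidence mask — a view, never a
destruction of labels. Zone extent statistics count pixel centers inside
each zone polygon (boundary counts as inside); class percentages are
reported over all zone pixels (primary) and additionally over confident
pixels only, since either convention is defensible.

## Synthetic scenes: what they emulate and what they do not

The generator renders a zonal layout (steppe matrix, a southern forest-steppe
band, shrub blobs in the west, bare patches near edges) at each date as
per-class mean RGB (phenology palette) + a class-specific correlated texture
field (Gaussian-filtered white noise with class-specific correlation length
and amplitude, standardized, persistent across dates) + per-date iid pixel
noise (sd 8). Palettes are built so that on *every* date at least one class
pair is color-confusable (steppe = forest-steppe early in the season while
their textures match; dried steppe ≈ bare land in August/September while
their textures nearly match) and every pair separates on some other date.
This is the property that makes any single-date model strictly worse than the
time-series model — the central behaviour the end-to-end tests check.

Default scene: 1024×1024 px (≈ 41 m square at 4 cm GSD), 6 dates, 17 survey
plots (0.5 m-radius circle sampling then yields ≈ 8.3 k steppe samples,
within 10 % of the emulated campaign's 8456), 123 shrub points, a 134-point
transect, 30 bare points, five rectangular observation zones. Everything is
a deterministic function of the master seed.

The generator emulates texture granularity, phenology and sampling geometry —
not plant shapes, shadows, BRDF/illumination drift, co-registration error, or
mosaicking seams. Passing tests therefore demonstrate that the pipeline
recovers class structure of the assumed kind (texture + phenology), not
performance on any particular real site.

## Problem sizes used by the benchmark runs

Chosen as desk-scale defaults for a single CPU:

* end-to-end study: the default 1024² scene, combined 444-feature
  descriptors, grouped CV over 32 units with 128-tree forests — pooled
  metrics are insensitive to ensemble size beyond ~100 trees, while the
  500-tree default would multiply runtime ~4× without changing the outcome;
* time-series vs single-date: a 384² scene with 6 plots sampled at 0.2 m
  radius (≈ 600 samples), 64-tree forests, 5 seeds;
* selection benchmark: n = 500, 5 informative + 50 noise features, 4 classes,
  adjacent class means exactly 2 sd apart (permuted grid), 20 seeds.

## Known limitations

* The "correlation"/"Haralick correlation" pair is redundant under symmetric
  accumulation (kept for the naming contract).
* Held-out permutation importance approximates, but does not equal, per-tree
  OOB permutation importance; rankings agree in practice but thresholds can
  differ from the reference R procedure.
* Geo I/O is plain TIFF plus a JSON sidecar (geotransform, GSD, CRS id);
  north-up grids with square pixels only, and no reprojection or resampling —
  mismatched grids are an error by design.
* Zone percentages over all pixels vs confident pixels differ when the
  low-confidence share is large; both are reported.
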