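# Methods

This note documents the models and procedures `ecogeo` implements, the
defaults it ships, the design decisions taken where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Grids, coordinates, and I/O

All rasters are geographic (WGS84 lon/lat decimal degrees), cell-centre
registered, square-celled, stored with row 0 at the northern edge.
Cell membership uses half-open intervals closed at the lower/left edge,
so every in-extent point belongs to exactly one cell; a point on the
grid's outer upper/right edge is outside. Rasters are read and written
as ESRI ASCII grids — a plain-text format whose `NODATA_value` is
honoured; NaN is always masked. A stack's shared mask is the
intersection of its layers' validity. Co-registration is enforced to
1e−9 degrees.

Occurrence CSVs (`species,lon,lat[,source]`) are cleaned by dropping
rows with missing or non-numeric coordinates (counted) and collapsing
byte-identical duplicates. Thinning keeps at most one record per grid
cell — the first in file order, a deterministic tie-break — and removes
records on masked cells. Clipping precedes thinning in the pipeline.

Habitat areas use the spherical-quadrilateral cell area
R²·Δλ·(sin φ_top − sin φ_bottom) with R = 6371.0088 km; a 2.5 arc-min
cell at the equator is ≈ 21.5 km².

## Predictor screening and ordinations

Variables are retained so that every pairwise Pearson |r| < 0.75 **and**
every variance inflation factor VIF_j = 1/(1 − R²_j) ≤ 10, the usual
collinearity convention. Which member of a flagged pair to drop is
under-determined; we drop the member with the larger mean absolute
correlation to all other variables, then prune the largest VIF until all
pass, ties broken by input column order. The result is scale-invariant
and deterministic. Zero-variance variables are removed with an explicit
reason; if fewer than two variables survive, a warning is recorded and
the pipeline falls back to the full layer set.

PCA operates on the correlation matrix (variables standardized to zero
mean, unit variance) because the layers' units are incommensurate;
variance-explained fractions therefore sum to 1. The discriminant
analysis uses priors proportional to group sizes and reports the
training-set classification table. Note that training accuracy of any
fitted linear rule carries an O(√(p/n)) optimism, which the permutation
test accounts for by using n large enough to make it negligible.

## Ensemble niche models

**Background.** Pseudo-absences are cell centres drawn uniformly (with
replacement) from the valid mask. Desk-scale default 10,000 points
(config-overridable up to the 200,000 a full study would use).

**Replicates.** Presences and background are split 70/30 independently
per replicate (rounded to nearest, at least one point per side). Default
10 replicates per family; a full study would use 100.

**Families.** All three families contrast presences against background
as a binomial response on features standardized by training mean/sd:

- *GLM* — logistic regression with linear + quadratic terms per
  variable (very weak ridge penalty for numerical stability). The
  fitted optimum on a variable is −b_lin/(2·b_quad) back-transformed.
- *Maxent-like* — ridge-penalized logistic regression on linear,
  quadratic, and hinge features (one-sided ramps at five training
  quantiles per variable, both orientations). Its suitability is the
  fitted probability rescaled by its maximum over the calibration grid,
  frozen at fit time.
- *MARS-like* — forward selection of paired hinge bases
  max(0, ±(z − k)) by residual sum of squares, then backward pruning on
  the generalized cross-validation score GCV = (SSE/n)/(1 − C(M)/n)²
  with the standard penalty of 3 per knot; additive (no interactions),
  predictions clipped to [0, 1]. Written in-package because no MARS
  implementation is available as a dependency.

Near-complete separation (|coefficient| > 50 on standardized features)
triggers a refit at 100× stronger penalty, recorded in fit metadata.

**Clamping.** Prediction clamps every variable to its training range
(the Maxent convention). Beyond the calibration envelope the quadratic
and hinge responses are unsupported extrapolations; clamping holds them
at the envelope boundary. This is what makes projection onto strongly
shifted scenario stacks behave: models of species indifferent to the
shifted variable keep their ranges instead of acquiring spurious
responses several standard deviations outside their training data.

**Evaluation.** AUC is computed by rank comparison (Mann–Whitney form;
tied pairs count ½) — identical to trapezoidal ROC integration. TSS =
sensitivity + specificity − 1 is maximized over all distinct score
thresholds with "predicted present" meaning score ≥ threshold; the
smallest argmax is reported.

**Ensembling.** Members with test-split TSS ≥ 0.8 are admitted; the
ensemble surface is their TSS-weighted mean and the binarization cutoff
the TSS-weighted mean of their TSS-maximizing thresholds. If no member
passes, an explicit "no admissible members" error is raised. With few
members and a single family the cutoff is noticeably noisy (the argmax
threshold is a high-variance statistic under class imbalance); the
three-family, ten-replicate default averages ~30 thresholds and
stabilizes it — coincident species then typically come out with RI < 0.1
rather than the ~0.15 noise floor a small single-family ensemble shows.

**Projection.** Scenario stacks are predicted by exactly the members
admitted into the current-climate ensemble, reusing its weights and
cutoff (transferability); multi-realization scenario sets are averaged
cellwise before projection.

## Niche statistics

Suitability surfaces are normalized to probability distributions over
the shared valid mask. Schoener's D = 1 − ½Σ|p−q|, Warren's
I = 1 − ½Σ(√p−√q)² = Σ√(pq) (so D ≤ I always), Levins'
B = 1/Σp² standardized to (B−1)/(n−1) ∈ [0, 1].

The niche identity test fits one fast family (GLM by default) per
species against a fixed background sample, pools the two occurrence
sets, repartitions them at random into pseudo-groups of the original
sizes, refits, and recomputes D and I per pseudoreplicate. The p-value
is the add-one estimator p = (1 + #{null ≤ observed})/(n_reps + 1),
one-tailed toward divergence, so p > 0 always and under exchangeability
P(p < 0.05) ≤ 0.05 exactly. The background is held fixed across
pseudoreplicates; refitting full multi-family ensembles per
pseudoreplicate would multiply cost by ~100 without changing the null's
logic. Levins' B is bootstrapped by resampling occurrences with
replacement (default 100 replicates; failures skipped and counted);
breadth samples are compared by a two-sided Mann–Whitney U (exact for
small tie-free samples, tie-corrected normal approximation otherwise).

## Isolation pipeline

RI is computed on **cell counts**, matching its definition; km²-weighted
RI is available as a config option. An empty range leaves that species'
RI undefined (NaN) with the pair reported, rather than silently 1.
The isolation-shift summary reports per-ordered-pair RI(scenario) −
RI(current) and their mean over all ordered pairs (12 for four species),
classifying each pair above/on/below the identity line.

`run_pipeline` seeds every random stage from one master seed, records a
config hash, seeds, retained layers, member counts and cutoffs in a JSON
manifest, and on stage failure writes a `FAILED` marker naming the
stage while keeping partial artifacts.

## The synthetic landscape

Environmental layers are Gaussian random fields: white noise smoothed
with a Gaussian kernel (autocorrelation length default 3 cells — chosen
so that on the default 200×200 grid the empirical cross-layer
correlations of an uncorrelated target stay within ±0.15), standardized,
then mixed per cell through an eigenvalue square root of the target
inter-layer correlation matrix, and finally placed on climate-like
scales (e.g. bio1 ≈ 8 ± 6 °C, bio12 ≈ 800 ± 300 mm). Smoothing-then-
mixing was chosen over spectral synthesis for simplicity and exact
reproducibility. The default extent mirrors a montane-China study
window (91–125° E, 20–47° N).

Virtual species follow the standard Gaussian-bell convention:
suitability = max_suitability · exp(−½ Σ_l ((x_l − c_l)/b_l)²).
Presences are drawn with probability proportional to suitability and
placed at cell centres (no jitter), making grid thinning exactly
testable. Scenario shifts are abstract cellwise affine transforms
x → x·factor + offset per layer; no attempt is made to mimic real GCM
structure.

**The four-species benchmark** (`four_species_system`) spans the
isolation spectrum on a temperature × precipitation plane: a nearly
coincident montane pair (optima 6.0 vs 6.3 °C, 930 vs 950 mm), a cold
southwestern species (2 °C), and a warm northern one (12 °C) — thermally
allopatric from the southwestern species at ~6.7 breadths' separation.
Precipitation optima are non-monotone in temperature so the pooled
occurrence table does not trip the collinearity screen. Breadths
(1.2 °C, 70 mm) are set so replicate models evaluate around TSS
0.85–0.95, i.e. the species are as well-modelled as the real montane
endemics this layout emulates and clear the TSS ≥ 0.8 gate across
landscape realizations. The southwestern species additionally requires
high December solar radiation (breadth 2000 kJ m⁻² day⁻¹), an axis the
others ignore; shifting srad12 by +6000 is therefore a *differential*
scenario that contracts and relocates only that species' range and
raises mean pairwise isolation. A uniform steepening or shift of a
shared gradient, by contrast, moves all species together and leaves RI —
a ratio of cell counts — nearly invariant; the differential response is
what turns scenario change into isolation change, as in the empirical
studies this emulates.

## Problem sizes and what the tests show

The shipped tests and the acceptance script run at desk scale: 40×40 to
200×200 grids, 50–150 occurrences per species, 1,000–10,000 background
points, 2–10 replicates per family, 99 identity-test pseudoreplicates,
50 outer seeds for calibration. These sizes make every stage's
statistical behaviour measurable (oracle agreement is exact regardless
of scale; calibration and recovery rates have binomial error bars quoted
in the tests).

What passing does **not** show: the generator produces stationary
Gaussian fields and clean, unbiased presence samples. Real occurrence
data carry spatial sampling bias, positional error, and non-Gaussian
environmental structure; real climate layers are strongly and
heterogeneously correlated. Results on the benchmark therefore validate
the machinery and its statistical contracts, not the ecological accuracy
of any particular real-world application.

## Known limitations

- Raster I/O is ESRI ASCII only; no GeoTIFF, no reprojection between
  coordinate systems.
- Model families are the three named above; no GAM/RF/BRT, no
  variable-importance metrics.
- The identity test's background is fixed across pseudoreplicates, and
  the bootstrap replicate count for Levins' B defaults to 100; both are
  configurable.
- Scenario stacks must share the calibration grid; no resolution
  changes between calibration and projection.
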