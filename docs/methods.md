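# Methods

This note documents the statistical model behind `soilfingerprint`, the
parameters that matter, the synthetic data model used to validate it, and
the numerical and design choices that were genuinely open.

## Data model and preprocessing

The unit of analysis is an attribute table: samples in rows, attributes
(KO, Pfam, TIGRFAM or genus annotations) in columns, non-negative integer
counts. Metadata carries six continuous soil factors — bulk density
(kg/dm³), CEC (cmol C/kg), total N (g/kg), pH, SOC (g/kg), clay (%) — and
an optional biome label. Missing factor values are tolerated and dropped
per analysis (decile splits, regressions and cross-validation each use
only the samples with the factor under study), never globally.

Sample filters use strict `>` against annotation-specific floors
(KO/Pfam 2,000; TIGRFAM 500; genus 4,000 total reads). Attribute
retention is a logical OR of two inclusive criteria: non-zero in at least
`ceil(0.5 * n_samples)` samples, or total count at least
`min_total_count`. The default constant 7,560 corresponds to an average
of 5 reads per sample over a 1,512-sample compilation;
`FilterPolicy.for_data_size(n)` rederives it as `5 * n` for other data
sizes. The prevalence denominator is the post-sample-filter count, and
the half-count rounds up — both choices are deterministic conventions
where the convention was unstated.

### TMM normalization

Between-sample scale factors follow the canonical trimmed mean of
M-values: the reference sample is the one whose 75th-percentile count
fraction is closest to the mean across samples; for every sample,
per-attribute log2 ratios (M) and mean log2 abundances (A) against the
reference are computed over attributes positive in both (pairwise
exclusion of zeros, no pseudocounts); the top and bottom `trim_m = 0.30`
fraction by M and `trim_a = 0.05` by A are discarded (rank-based,
two-sided); the factor is 2 to the precision-weighted mean of the
surviving M values, with inverse approximate-binomial (delta-method)
variances as weights; factors are rescaled to geometric mean 1. The trim
fractions are the cited method's standard defaults and are exposed in
configuration. The implementation agrees with Bioconductor edgeR's
`calcNormFactors(method="TMM")` to ten decimal places on test fixtures,
and with an independently coded plain-Python oracle to full precision.

One property worth stating precisely: factors are exactly invariant to a
pure depth change only in the limit — M and A are depth-free, but the
precision weights shift with absolute depth, so rescaling one sample's
counts ten-fold moves factors by about 1%. This matches the reference
implementation and is inherent to precision weighting.

Normalized values are TMM-adjusted counts per million:
`count / (library_size * factor) * 1e6`. Whether the original analysis
kept CPM or library-scaled counts after TMM is not documented; CPM is
this package's convention and is flagged in the table provenance header.

## Breakpoint segmentation

Sorted importance, abundance and CV curves are segmented with an
intercept-only (piecewise-constant) least-squares structural-change
model. Admissible segments have length at least
`max(min_segment, ceil(h * n))` with defaults `min_segment = 2`,
`h = 0.01`. For each candidate break count m = 0..`max_breaks` (default
5) the globally optimal segmentation is found by dynamic programming
(O(max_breaks · n²), exact); m is selected by
`BIC(m) = n log(RSS_m / n) + (2m + 2) log n` (m break positions, m+1
means, one variance), with ties resolved toward fewer breaks and an
RSS floor of `n · range² · 1e-12` guarding the log at numerically zero
residuals. The segmentation is invariant to adding a constant and
equivariant under positive scaling. Equality with exhaustive enumeration
is asserted in tests for all series up to length 12.

Two cut rules are used, matched to the curve type:

- **Abundance and CV curves** (cluster fingerprints): the *first
  segment* of the segmentation of the log10 curve. These decay roughly
  exponentially; on the raw scale the residuals of the top few values
  dominate the fit, whereas on the log scale the head plateau is tight
  and the cut is scale-free. Note a structural consequence of the
  minimum segment size: a single overwhelmingly abundant attribute still
  yields a head of at least `min_segment` members.
- **Importance curves** (supervised fingerprints): the maximal *leading
  run of segments whose mean importance clears a noise band*
  (`noise_z = 2.0` by default). The scaled importance is a z-statistic,
  and its noise floor has internal structure that BIC legitimately
  resolves (attributes used by a single tree sit near z ≈ 1, unused ones
  at exactly 0, below-chance ones negative), while the signal decay
  itself may also be split into several regimes. Cutting at the first
  break truncates the signal; cutting at the last break absorbs the
  noise beds. Requiring a segment's mean to exceed the conventional
  two-standard-error band keeps exactly the segments distinguishable
  from noise, regardless of how many regimes either side has. The
  constant 2 is the ordinary z-test convention, not a fitted value.

## Supervised fingerprints

For factor contexts, the lowest and highest `floor(0.10 * n)` samples by
factor value form the two groups (stable sort on value then sample id;
constant factors are an error). For biome contexts the grouping is
one-vs-rest. A 500-tree random-forest classifier (scikit-learn defaults,
`max_features=sqrt`) is fitted, and importance is computed per tree on
its out-of-bag samples: baseline accuracy minus accuracy after permuting
one attribute's values among the out-of-bag rows, averaged over trees and
divided by the standard error over trees. Attributes a tree never splits
on contribute exact zeros. This is the scaled (mean/SE) permutation
importance convention of classical random-forest implementations;
ensemble-level permutation importance was deliberately not used because
it masks redundant informative attributes (permuting one of many
correlated predictors barely degrades an ensemble that can consult the
others), which would defeat recovery of co-varying attribute sets.

Members of the selected head are signed by the OLS slope of their
normalized abundance on the factor value over all samples (biome
indicator 0/1 for biomes): positive slope → "high" fingerprint, negative
→ "low". Zero-variance attributes are excluded. Slope, Pearson
correlation and its p-value are recorded per member. Direction
assignment is exactly antisymmetric: negating the factor swaps the two
fingerprints.

## Model-quality gate

Fingerprints are only extracted for contexts a forest can actually
predict. Per repeat (5 total), samples are split 50/50 into training and
test halves; 10-fold cross-validation inside the training half yields
50 per-fold scores (reported, never hidden), and the gate statistics —
RMSE and variance explained — are the means over the held-out halves.
The response is z-scored first so the single RMSE threshold is
comparable across factors with different units; this standardization is
flagged in every report. The gate passes at RMSE < 0.8 (strict) OR
variance explained ≥ 0.60 (inclusive); "and/or" is read as OR, with AND
available in configuration. The regression forest uses 100 trees and
`max_features = 1/3` (the regression-forest convention); the tree count
is a cost/stability trade-off documented here rather than a tuned value.

## Unsupervised fingerprints

K-means runs on standardized `log1p` CPM values (raw CPM would let a few
abundant attributes dominate the Euclidean metric) over the full
post-filter attribute space. Samples are canonically sorted by id before
fitting, and cluster labels are renumbered 1..k by first appearance, so
the assignment is invariant to input row order. k is scanned over 2–12
(10 restarts per k) and chosen by maximal mean silhouette; the
within-cluster sum-of-squares elbow curve is reported alongside for
inspection.

Per cluster, the per-sample total normalized abundance (sum over all
retained attributes) is regressed on each factor over that cluster's
samples; under TMM-CPM this total equals `1e6 / factor`, so the
regressions measure how the inferred compositional scaling tracks the
environment. Significance uses alpha = 0.05 without multiplicity
correction (configurable). Clusters with fewer than 3 samples are marked
unusable; constant factors are skipped. The selected cluster maximizes
the number of significant factors, ties broken by mean R² over the
significant ones. Its fingerprints are the breakpoint heads of the
within-cluster total-abundance curve and the coefficient-of-variation
curve (sd/mean, ddof=1, zero-mean attributes excluded).

## Synthetic data model

The generator states its own model in full. Factors are uniform within
the compilation's observed ranges (bulk density 0.28–1.56 kg/dm³, CEC
7.7–68.7, N 0.25–22.4, pH 4.4–8.3, SOC 2.4–510.9, clay 2.7–57.1%).
Expected relative abundance of a planted attribute is
`baseline * exp(effect_size * z)` where z is the factor scaled to
[-1/2, 1/2] over its range, so `effect_size` is the natural-log fold
change across the full gradient; background attributes have zero effect.
Counts are negative binomial (gamma-Poisson, dispersion 0.3) under
log-normal library sizes (median 30,000 reads, sigma 0.6). Background
baselines are log-normal (sigma 1.0) with a 10% sparse tail (x0.02) so
the prevalence/total-count filter is genuinely exercised. Defaults: 300
samples, 500 background attributes, 20 up + 20 down planted on pH with
`effect_size = 2.0` — a strong but realistic gradient response (about
7.4-fold across the range), chosen once as the reference recovery
condition.

The fertile scenario plants one coordinated-environment cluster: a 25%
sample subset receives factor quantiles driven by a latent fertility
score f in [-1, 1] (SOC/N/CEC up, bulk density/clay down), a set of 40
"moderate" attributes uniformly elevated 3-fold times `exp(0.5 f)` that
carries the clustering signal and the totals-vs-factor trend, and 6
"spike" attributes switched on in a fixed 16% of fertile samples at a
high level, making them simultaneously the most abundant and the most
variable attributes within the cluster — the planted fingerprint that
the abundant/variable head cuts must contain. Separating the two planted
roles is deliberate: a set can only be a well-posed breakpoint head if
its within-cluster abundance plateau is tight, while the clustering and
regression signals need many moderately shifted attributes.

What the generator does **not** emulate: phylogenetic correlation among
genera, spatial autocorrelation, biome-specific attribute co-occurrence
structure, annotation noise, or compositional interactions beyond the
common denominator. Passing recovery tests therefore demonstrates that
the pipeline's inference machinery is correct under its stated
assumptions, not that those assumptions hold for any particular real
soil compilation.

## Problem sizes and determinism

Recovery tests run at the generator defaults (300 x 540 supervised;
200 x 346 fertile); the gate check uses 200 x 140, sizes at which a
single run completes in seconds on one CPU while leaving the planted
effects at realistic magnitudes. All randomness flows from explicit
integer seeds (NumPy `default_rng`, scikit-learn `random_state`); every
CLI entry point is bit-reproducible under a fixed `--seed`, which the
test suite asserts byte-for-byte.

## Known limitations

- The importance noise-band cut assumes the importance statistic is a
  z-score; plugging in an unscaled importance would require a different
  `noise_z`.
- With strongly correlated planted attributes the per-tree out-of-bag
  importance spreads credit; very weak effects (z below ~2) are
  indistinguishable from the noise floor by construction and yield
  empty fingerprints rather than unstable ones.
- The cluster-selection statistic (total abundance vs factor) is
  meaningful under TMM-CPM only through the normalization factor; a
  different normalization would change its interpretation.
- TIGRFAM-like data with globally weak structure are expected to fail
  the gate or yield clusters with few significant correlations; the
  package reports the statistics and lets the configured thresholds
  decide rather than defining "satisfactory" ad hoc.
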