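# soilfingerprint

Genomic fingerprints of soil microbiomes: a tested pipeline for finding
the microbial attributes (KEGG orthologies, Pfam/TIGRFAM protein families,
or read-based genera) whose abundances most strongly track soil
environmental gradients, biomes, or emergent sample clusters.

The package is aimed at microbial ecologists working with per-sample
functional or taxonomic profile tables (samples x attributes, integer
counts) and matched soil metadata — bulk density (kg/dm³), cation exchange
capacity (cmol C/kg), total nitrogen (g/kg), pH, soil organic carbon
(g/kg) and clay content (%) — the six factors most often associated with
soil microbiome structure.

## The method

**Preprocessing.** Samples with too few total reads are removed
(annotation-type-specific floors: KO/Pfam > 2,000, TIGRFAM > 500, genus
> 4,000), then attributes are kept only if they are non-zero in at least
half of the samples *or* reach a total count equivalent to an average of
5 reads per sample (7,560 over a 1,512-sample compilation). Surviving
counts are scaled between samples by trimmed-mean-of-M-values (TMM)
normalization — doubly trimmed (30% on log-ratios M, 5% on mean log
abundance A), precision-weighted log2 ratios against a reference sample —
and expressed as counts per million.

**Supervised fingerprints.** For a factor *x*, samples in the lowest and
highest decile of *x* form two groups (for biomes: one-vs-rest). A random
forest (500 trees) classifies the groups, and every attribute *j* is
scored by scaled out-of-bag permutation importance,

&nbsp;&nbsp;&nbsp;&nbsp;*z<sub>j</sub>* = mean<sub>t</sub>(Δacc<sub>jt</sub>) / SE<sub>t</sub>(Δacc<sub>jt</sub>),

the per-tree out-of-bag accuracy decrease under permutation of *j*,
divided by its standard error across trees. Because importances decay
steeply and then flatten into a noise floor, the sorted importance curve
is segmented by least-squares piecewise-constant breakpoint analysis
(dynamic programming, minimum segment size 2 and minimum segment fraction
h = 0.01, break count by BIC); the selected set is the leading run of
segments whose mean *z* clears the two-standard-error noise band. Each
selected attribute is then regressed (OLS) on *x* over **all** samples:
positive slopes form the high-*x* fingerprint, negative slopes the
low-*x* fingerprint, each member carrying its importance, slope and
Pearson correlation. A context only yields fingerprints when a
cross-validated random-forest regression (10-fold CV repeated 5 times
inside a 50% training half, scored on the held-out half, response
z-scored) clears the quality gate RMSE < 0.8 **or** variance explained
≥ 60%.

**Unsupervised fingerprints.** Samples are clustered by k-means on
standardized log1p CPM profiles (k scanned 2–12; elbow and silhouette
recorded, k chosen by silhouette). For every cluster, each sample's total
normalized abundance is regressed on each of the six factors; the cluster
with the most significant correlations (ties by mean R²) is selected, and
its fingerprint is extracted by breakpoint head cuts on the attributes
sorted by within-cluster total abundance ("most abundant") and by
coefficient of variation ("most variable").

**Synthetic data.** Because compilation-scale metagenome collections are
not redistributable, `soilfingerprint.synthetic` generates tables with
the statistical structure the method assumes — log-normal library sizes,
negative-binomial counts, sparse background attributes, attributes whose
relative abundance changes by a chosen natural-log fold across a factor's
range, and a "fertile" sample subset with coordinated SOC/N/CEC increases
and bulk-density/clay decreases — together with the planted ground truth,
so every stage is verifiable by recovery testing.

## Worked example

```bash
fingerprint simulate --scenario gradient --seed 7 --out-dir data
# wrote 300 samples x 540 attributes to data

fingerprint supervised --table data/counts.tsv --type ko \
    --env data/metadata.tsv --factor ph --seed 7 --out ph_fingerprint.json
# ph: 20 high / 20 low members
```

The simulated table plants 20 attributes rising and 20 falling with pH
(two natural-log folds across pH 4.4–8.3) among 500 background
attributes; `truth.json` records which. The run above passes the quality
gate, and the two reports in `ph_fingerprint.json` recover exactly the 40
planted attributes with correct signs. Each member carries the statistics
used to select it, e.g.

```json
{
  "attribute_id": "K00514",
  "importance": 5.422984249854101,
  "slope": 978.5902125346267,
  "correlation": 0.6683833707312129,
  "p_value": 3.4241903853553004e-40
}
```

(`importance` is the scaled out-of-bag importance *z*; `slope` is CPM per
pH unit over all 300 samples.)

The unsupervised route on the fertile scenario:

```bash
fingerprint simulate --scenario fertile --seed 7 --out-dir fert
fingerprint unsupervised --table fert/counts.tsv --type ko \
    --env fert/metadata.tsv --seed 7 --out clusters.json
# selected cluster 1 of k=2: 6 abundant / 6 variable members
```

Cluster 1 (50 samples) shows 5 of 6 factors significantly correlated with
total normalized abundance (e.g. SOC: slope +1265 CPM per g/kg,
R² = 0.23, p = 4.9e-4) versus 0 for the other cluster, and both the
abundant and the variable fingerprint recover the 6 planted spike
attributes.

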