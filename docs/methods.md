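# Methods

## Model and procedure

`melimmune` treats bulk tumor expression as a superposition of tumor-
intrinsic transcription and transcripts contributed by infiltrating immune
cells.  Each of 24 immune cell types is represented by a set of marker genes
assumed specific to it; the mean standardized expression of those genes in a
sample is taken as a monotone proxy for that cell type's abundance.  Three
assumptions matter:

- **Specificity after lineage filtering.**  Marker genes expressed highly by
  the tumor lineage itself are removed before scoring: a gene is discarded
  when its expression ranks in the top `top_fraction` (default 0.25) of a
  whole-transcriptome melanoma or melanocyte reference profile.  Ranks are
  scale-invariant, so raw or normalized reference intensities give the same
  filter; the input scale is deliberately left to the caller.  Rank ties at
  the boundary all count as highly expressed (conservative removal,
  independent of sort stability).  By default a gene is removed when it is
  highly expressed in *any* reference ("any" rule); requiring *all*
  references is available.  Control-tissue labels (colon cancer line,
  mucosa, blood/lymph vessels) are dropped by a label blocklist before
  filtering.
- **Composite cell types.**  Genes listed under both NK subtypes are
  relabeled generic NK; genes under every cytolytic subtype (NKb, NKd, CD8 T
  cells, Tgd) become cytotoxic-cell markers; genes under two or more of
  {Th1, Th2, CD8 T cells, Tem, Tcm} become generic T-cell markers.  Rules
  apply in that order (most specific first); after relabeling the 24 gene
  sets are disjoint, so the total score never double-counts a gene.
  Relabeling is idempotent; a rule member that an earlier rule (or a
  previous application) consumed is tolerated, while a label foreign to the
  compendium raises an error.
- **Within-cohort standardization.**  All clustering and scoring operates on
  per-gene z-scores (sample variance, n−1).  Replication cohorts are
  standardized independently before centroid projection, so cross-cohort
  intensity scales never mix.

### Cluster discovery

Samples are clustered by resampling consensus: each repetition draws
⌈0.8·n⌉ samples and ⌈0.8·g⌉ signature genes, runs k-means (k-means++
initialization, 10 restarts, Euclidean distance), and the consensus matrix
entry for a sample pair is the fraction of co-clustering runs among runs
where both were drawn.  K is selected from the empirical CDF of the
n(n−1)/2 consensus values: with distinct sorted values u_j augmented by
{0, 1}, `AUC(K) = Σ_j (u_j − u_{j−1})·CDF(u_{j−1})`, the relative Δ-area is
`delta(K) = (AUC(K) − AUC(K−1))/AUC(K−1)` (and `delta(2) = AUC(2)`), and the
selected K is the largest with `delta ≥ 0.03`.  The 0.03 threshold
operationalizes the usual visual "elbow" reading of Δ-area plots; because
published analyses of this kind chose K by inspection, a manual override is
first-class and logged.  Final labels cut an average-linkage dendrogram of
(1 − consensus) at K — the convention of the standard consensus-clustering
packages.  A sample pair never co-drawn gets consensus 0 with a warning
(practically unreachable at the default 5000 repetitions).  Gene clusters
come from a single k-means pass (fixed K = 4) over gene profiles with
samples fixed in their clusters; labels are renumbered by first appearance
so runs are reproducible.

### Projection

A cluster centroid is the per-gene mean standardized expression of its
members.  A new sample joins the centroid with the highest Spearman rank
correlation over the shared genes (average ranks on ties; cluster ties break
toward the lowest index and are logged).  At least 3 shared genes are
required, and losing more than 25% of the centroid genes is an error —
beyond that the rank correlation no longer reflects the discovered profile.

### Scores

Unit scores are min-max rescaled per cohort (each type attains 0 and 1
within the cohort); projected cohorts rescale within themselves, since
cross-cohort calibration of array vs RNA-seq intensities is not meaningful.
A constant raw column is set to 0.5 with a warning.  The Th1/Th2 ratio is
reported with 0/0 as missing and x/0 flagged infinite (the Th2-minimum
sample always has unit score 0, so an infinite ratio for one sample is
expected, and logged rather than warned).  The pathway gene set defaults to
the nine Wnt/β-catenin genes with "TCF1" resolved to the modern symbol TCF7
(the historic alias is ambiguous between TCF7 and HNF1A; the choice is a
config override).  When a cohort lacks pathway genes, at least 7 of 9 must
be present and the sum is rescaled by 9/present — keeping scores comparable
across cohorts with different coverage.  Missing methylation β values are
imputed with the gene's cohort mean (logged); β outside [0, 1] is an error.

### Statistics

- Fisher's exact test is two-sided by the "sum of table probabilities not
  exceeding the observed" convention with 1e-7 relative slack (delegated to
  scipy, cross-checked in the test suite against an in-repo fixed-margin
  enumeration oracle for every table with total ≤ 30).  The convention is
  stated because printed p values from other variants (mid-p, one-sided,
  χ²) can differ at the second digit.  The reported odds ratio is the
  sample ratio ad/(bc), infinite when bc = 0 and ad > 0.
- The enrichment family is (non-empty gene clusters) × (cell types);
  the realized m is logged and the Bonferroni threshold is exactly α/m.
- The biomarker cutpoint search scans every midpoint of consecutive
  distinct predictor values leaving at least 10% of samples on each side,
  scores each by the pooled-variance two-sample t statistic of the
  response, and returns the |t|-maximizing cut (ties toward the smaller
  cut).  Zero pooled variance flags the statistic infinite; a search where
  no cut discriminates raises.  This operationalizes the "means test" of
  the X-tile cutpoint tool, whose exact internals are unpublished.
- Cox models use lifelines' partial likelihood with Efron tie handling;
  Wald 95% CIs and p values are reported.  Monotone likelihood (perfect
  separation) is detected via convergence warnings and flagged
  (`converged=False`) rather than raised.  Stratum-specific immune-score
  effects are separate fits within each driver stratum; strata without
  events are skipped with a warning.
- In the discovery pipeline the "poor-prognosis cluster vs rest" indicator
  is automated as the discovered cluster with the lowest mean total immune
  score (labels are arbitrary integers; the published poor-prognosis
  cluster is exactly the lowest-immune one).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the biology of any specific dataset:

- **Clusters.**  Six planted clusters with default proportions
  11/21/13/25/15/15% (the published cluster sizes).  Cluster identities
  mirror the published phenotypes: low-immune with NKb/Treg excess (1),
  high immune (2), intermediate adaptive-skewed (3), lowest immune (4),
  intermediate innate-skewed keratin-rich (5), low-immune keratin-rich (6).
  Each cluster's 24-type infiltration profile carries a fixed ±25%
  per-type modulation (coprime index patterns, so orderings differ across
  clusters): real infiltrates differ in composition, not just level, and
  without composition differences the standardized centroid of a uniformly
  infiltrated cluster is nearly constant across genes, making
  rank-correlation projection uninformative.  The worst-separated cluster
  pair differs by ≥ 0.8 infiltration units on its most discriminating cell
  type — 4× the default noise SD (0.2), the separation regime the tests
  target.
- **Expression.**  Signature gene of type t:
  `baseline + effect·infiltration[s,t] + N(0, noise_sd)` with baseline 6.0
  (log-scale-like), effect 1.0 per infiltration unit.  A 40-gene keratin
  block gains +2.0 in clusters 5–6; 1000 background genes are baseline plus
  noise; the nine pathway genes follow
  `baseline − 0.8·infiltration[s, T cells] + noise`, making pathway
  expression highest where T-cell infiltration is lowest (cluster 4), the
  planted analogue of the observed β-catenin/T-cell anti-correlation.
- **Molecular layers.**  Promoter β = 0.5 − 0.3·(centered pathway
  expression) + N(0, 0.05), clamped to [0, 1] with a warning; mutation flags
  Bernoulli(0.03); amplification calls (+2) Bernoulli with per-cluster rate
  (0.05, elevated to 0.14 in cluster 4 — the published 19/133 vs 12/235
  contrast); deletions (−2) at 0.01.  The layers take the realized
  expression matrix as an argument so β anti-correlates with the actual
  noise realization, not just the deterministic mean.
- **Survival.**  Exponential event times with hazard
  `baseline_rate·exp(ln(1.7)·1{cluster 4} + lhr[stratum]·(score − mean))`,
  baseline rate 0.05 events per unit time, stratum coefficients per unit
  total score: WT −0.8, BRAF −0.4, NRAS 0 (the qualitative published
  interaction).  The score enters mean-centered — a reparameterization that
  leaves every hazard ratio unchanged while keeping `baseline_rate`
  interpretable at the cohort-average score.  Censoring is independent
  exponential with hazard `baseline_rate·c/(1−c)` for censor fraction
  c = 0.3; c = 0 disables it.  Strata are drawn with proportions
  BRAF/NRAS/WT = 0.40/0.25/0.35.
- **Reproducibility.**  One root seed feeds named substreams
  (expression / layers / survival), so layers can be regenerated
  independently and every output is bit-identical under a fixed seed.

What the generator does **not** emulate: count-based RNA-seq noise,
batch/platform effects, probe artifacts, correlated infiltration within a
cluster, tumor purity variation, or non-proportional hazards.  Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes at realistic separations — not that the assumptions hold in any
particular real dataset.

## Problem sizes

Tests and the acceptance script run at desk scale: consensus sweeps use
n = 300 samples, 380 signature genes, 250 repetitions, K ≤ 12 (the full
protocol default is 5000 repetitions; 250 already gives consensus-entry
SDs well below the Δ-area decision margin at these separations); survival
recovery uses n = 700 with 50 seeds.  Integration tests use n = 120 with a
K override, since the Δ-area rule needs the larger cohort to resolve six
clusters reliably.

## Known limitations

- The Δ-area threshold (0.03) is a heuristic replacement for visual
  inspection; cohorts with weak separation may need the manual override.
- Exact numeric parity with any particular consensus-clustering package is
  not claimed; parity with the formulas above is tested.
- The cutpoint search is an interpretation of the X-tile means test; other
  implementations may place ties differently.
- Min-max score rescaling makes unit scores cohort-relative: absolute
  values are not comparable across cohorts, only orderings and
  within-cohort contrasts.
- Fisher p values for strong enrichments are method-sensitive at the
  printed-precision level (see the convention note above).
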