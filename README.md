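# melimmune

Immune-landscape analysis of melanoma bulk transcriptomes.

Primary cutaneous melanomas differ widely in how strongly the host immune
system has infiltrated them, and that difference predicts survival.
`melimmune` implements an end-to-end, reproducible version of the
immunome-clustering workflow used to chart that landscape:

1. **Signature compendium** — a curated table of genes each specific to one
   of 24 immune cell types (11 innate, 13 adaptive), with composite labels
   (NK from the CD56-bright/dim subtypes, cytotoxic cells, broader T cells)
   and a tumor-lineage filter that removes any gene ranking in the top 25%
   of a melanoma/melanocyte reference transcriptome — so tumor-intrinsic
   expression cannot masquerade as infiltration.
2. **Consensus immunome clusters (CICs)** — resampling consensus clustering
   of samples on the signature genes (k-means, Euclidean distance, 80%
   sample and gene subsampling), with K chosen from the relative change in
   the area under the consensus-value CDF (Δ-area) and final labels from
   average-linkage clustering of the consensus dissimilarity.  Discovered
   clusters are projected onto replication cohorts by nearest centroid under
   Spearman rank correlation, and genes are grouped by a one-pass k-means
   (K = 4) with samples fixed in their clusters.
3. **Scores** — per cell type *t* and sample *s*,
   `raw[s,t] = mean(z(g) : g ∈ signature(t))` on per-gene standardized
   expression, min-max rescaled to [0, 1]; the total immune score sums all
   24 types, with innate/adaptive subtotals and the Th1/Th2 ratio.  For the
   9-gene Wnt/β-catenin pathway set (*CTNNB1, MYC, APC, APC2, SOX2, SOX11,
   TCF7, TCF12, VEGFA*): `gx_score = Σ gx` (standardized expression),
   `methyl_score = Σ (1 − β)` (promoter methylation), and
   `mutCNV_score = Σ (I + J)` with `I ∈ {0,1}` the activating-mutation flag
   and `J ∈ {−1,0,+1}` from deletion/amplification calls, plus their running
   combinations.
4. **Statistics** — Fisher exact enrichment of cell types within gene
   clusters with Bonferroni control (α/m), Kruskal-Wallis and ANOVA variance
   explained, Spearman correlation, an optimal means-test cutpoint for
   dichotomizing a biomarker, and Kaplan-Meier/log-rank and Cox
   proportional-hazards survival models, including immune-score effects per
   driver-mutation stratum (*BRAF*-V600, *NRAS* codon 12/13/61, double-WT).
5. **Synthetic cohorts** — a seeded generator plants 6 clusters with
   cluster-specific infiltration profiles, a keratin gene block, pathway
   expression anti-correlated with T-cell infiltration, methylation/mutation/
   CNV layers, and exponential survival with cluster- and stratum-specific
   hazards, so every stage is testable without any external download.

## Worked example

```python
import pandas as pd
import melimmune as mi

comp = mi.synthetic_compendium()                      # 380 genes, 24 cell types
cfg = mi.SyntheticConfig(n_samples=300, seed=1,
                         log_hr_score={"WT": 0.0, "BRAF": 0.0, "NRAS": 0.0})
X, truth = mi.generate_cohort(cfg, comp)              # 6 planted clusters

Z = mi.standardize_genes(X).restrict_genes(comp.genes)
sweep = mi.consensus_sweep(Z, mi.ConsensusParams(k_max=12, reps=250, seed=1))
print("selected K:", sweep.k_selected)

labels = sweep.selected.labels_series()
scores = mi.score_cells(Z, comp)
print(scores.summary["total"].groupby(labels).mean().round(2).to_string())

clin = mi.generate_survival(truth, scores.summary["total"], cfg)
low = scores.summary["total"].groupby(labels).mean().idxmin()
ind = pd.DataFrame({"low_immune": (labels == low).astype(int).to_numpy()})
cox = mi.cox_fit(clin["time"], clin["event"], ind)
row = cox.summary.loc["low_immune"]
print(f"low-immune cluster vs rest: HR={row['hr']:.2f} "
      f"(95% CI {row['ci_lower']:.2f}-{row['ci_upper']:.2f}, p={row['p']:.3f})")
```

prints

```
selected K: 6
cluster
1     1.09
2     8.49
3    11.70
4    11.01
5    22.81
6     4.32
low-immune cluster vs rest: HR=1.48 (95% CI 1.08-2.01, p=0.014)
```

The Δ-area rule recovers the planted K = 6.  Discovered cluster 1 is the
low-immune group (mean total score 1.09 of a possible 24) and cluster 5 the
high-immune group (22.81).  The cohort was generated with a hazard ratio of
1.7 for the low-immune cluster, and the fitted Cox confidence interval
(1.08–2.01) covers that value.

## Command line

`melimmune` exposes the same steps as subcommands:

```sh
melimmune simulate --outdir cohort --seed 3 --n-samples 300
melimmune derive-signature --signatures sig.tsv --profile skmel28.tsv --out imm.gmt
melimmune cluster --expr cohort/expression.tsv --signatures cohort/signatures.tsv \
    --kmax 12 --reps 5000 --seed 3 --outdir run
melimmune project --expr replication.tsv --centroids run/centroids.tsv
melimmune score --expr cohort/expression.tsv --signatures cohort/signatures.tsv \
    --methyl cohort/methylation.tsv --mut cohort/mutations.tsv --cnv cohort/cnv.tsv \
    --out scores.tsv
melimmune associate --scores scores.tsv --clinical cohort/clinical.csv \
    --labels run/labels.tsv --strata
melimmune run-discovery --config pipeline.yaml       # the whole thing at once
```

`run-discovery` standardizes, filters the compendium, splits train/test
(two-thirds/one-third), clusters the training set, projects the test set,
pools, and writes labels, centroids, gene clusters, scores, enrichment and
survival tables with a checksummed manifest; `run-projection` applies saved
centroids to a replication cohort.

## Layout

- `src/melimmune/compendium.py` — signature table I/O, composite labels, lineage filter
- `src/melimmune/synthetic.py` — planted-cohort generator
- `src/melimmune/preprocess.py` — standardization, train/test split
- `src/melimmune/consensus.py` — consensus clustering, Δ-area, centroids
- `src/melimmune/scoring.py` — cell-type and pathway scores
- `src/melimmune/stats.py` — enrichment, cutpoint, survival statistics
- `src/melimmune/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
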