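"""Synthetic melanoma cohorts with planted immune structure.

Generates bulk expression with six planted tumor clusters whose immune-cell
infiltration profiles drive signature-gene expression, a keratin gene block in
two clusters, nine Wnt/beta-catenin pathway genes anti-correlated with T-cell
infiltration, promoter-methylation beta values anti-correlated with pathway
expression, mutation/amplification calls with amplification enrichment in the
low-immune cluster, and exponential survival times whose hazard depends on
cluster membership and (stratum-specific) immune score.  Every downstream
stage of the analysis is therefore testable against known ground truth.

The default configuration encodes the study conditions of the published
primary-melanoma cohort: cluster proportions 11/21/13/25/15/15%, a poor-
prognosis low-immune cluster 4 with hazard ratio 1.7 versus the rest, and
immune-score effects that are protective in double-WT tumors, weaker in
BRAF-mutant, and absent in NRAS-mutant tumors.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compendium import ADAPTIVE_TYPES, INNATE_TYPES, SignatureCompendium
from .preprocess import ExpressionMatrix

__all__ = [
    "CELL_TYPES",
    "PATHWAY_GENES",
    "SyntheticConfig",
    "SyntheticTruth",
    "synthetic_compendium",
    "default_infiltration_means",
    "generate_cohort",
    "generate_molecular_layers",
    "generate_survival",
    "write_cohort",
    "substream",
]

#: The 24 scored immune cell types (11 innate + 13 adaptive).
CELL_TYPES = INNATE_TYPES + ADAPTIVE_TYPES

#: Wnt/beta-catenin signaling gene set used for the pathway scores
#: (TCF1 resolved to the modern symbol TCF7).
PATHWAY_GENES = ("CTNNB1", "MYC", "APC", "APC2", "SOX2", "SOX11", "TCF7", "TCF12", "VEGFA")

STRATA = ("BRAF", "NRAS", "WT")


def substream(seed: int, name: str, *extra) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one root seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key, *extra)))


def default_infiltration_means() -> np.ndarray:
    """6 x 24 mean infiltration (arbitrary units) per cluster per cell type.

    Cluster identities mirror the published phenotypes:
    1 low immune with excess CD56-bright NK and Treg, 2 high immune,
    3 intermediate adaptive-skewed, 4 lowest immune, 5 intermediate
    innate-skewed (keratin rich), 6 low immune (keratin rich).

    On top of these class levels each cluster carries its own fixed per-type
    modulation (+/-25%), because real infiltrates differ in composition, not
    just overall level; without within-cluster composition differences the
    standardized centroid of a uniformly infiltrated cluster would be nearly
    constant across genes and rank-correlation projection would be
    uninformative.  The worst-separated cluster pair still differs by >= 0.8
    infiltration units on its most discriminating cell type (4x the default
    noise SD).
    """
    types = list(CELL_TYPES)
    innate = np.array([t in INNATE_TYPES for t in types])
    level = np.zeros((6, 24))
    level[0, :] = 0.3
    level[0, types.index("NKb")] = 2.2
    level[0, types.index("Treg")] = 1.8
    level[1, :] = 2.5
    level[2, :] = np.where(innate, 0.6, 1.8)
    level[3, :] = 0.1
    level[4, :] = np.where(innate, 1.8, 0.6)
    level[5, :] = 0.9
    mult = np.array([1, 5, 7, 11, 13, 17])  # coprime to 24: distinct orderings
    c_ix, t_ix = np.meshgrid(np.arange(6), np.arange(24), indexing="ij")
    modulation = 0.75 + 0.5 * ((mult[c_ix] * t_ix + c_ix) % 24) / 23.0
    return level * modulation


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults encode the study conditions."""

    n_samples: int = 300
    cluster_proportions: tuple = (0.11, 0.21, 0.13, 0.25, 0.15, 0.15)
    infiltration_means: np.ndarray = field(default_factory=default_infiltration_means)
    baseline: float = 6.0            # mean log-scale expression of an unshifted gene
    signature_effect: float = 1.0    # expression shift per infiltration unit
    noise_sd: float = 0.2            # residual SD on every gene
    n_background_genes: int = 1000
    keratin_n_genes: int = 40
    keratin_shift: float = 2.0
    keratin_clusters: tuple = (5, 6)
    pathway_coupling: float = -0.8   # pathway expression per T-cell infiltration unit
    methyl_coupling: float = -0.3    # promoter beta per unit pathway expression
    methyl_noise_sd: float = 0.05
    mut_rate: float = 0.03
    amp_rate_by_cluster: tuple = (0.05, 0.05, 0.05, 0.14, 0.05, 0.05)
    del_rate: float = 0.01
    baseline_rate: float = 0.05      # events per unit time at cohort-average covariates
    log_hr_cluster4: float = float(np.log(1.7))
    log_hr_score: dict = field(
        default_factory=lambda: {"WT": -0.8, "BRAF": -0.4, "NRAS": 0.0}
    )
    censor_rate: float = 0.3
    stratum_proportions: tuple = (0.40, 0.25, 0.35)  # BRAF, NRAS, WT
    seed: int = 0

    def __post_init__(self) -> None:
        self.infiltration_means = np.asarray(self.infiltration_means, dtype=float)
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if abs(sum(self.stratum_proportions) - 1.0) > 1e-9:
            raise ValueError("stratum_proportions must sum to 1")
        if self.infiltration_means.shape != (6, 24):
            raise ValueError("infiltration_means must be 6 x 24")
        if (self.infiltration_means < 0).any():
            raise ValueError("infiltration means must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        for name in ("mut_rate", "del_rate", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= r <= 1.0 for r in self.amp_rate_by_cluster):
            raise ValueError("amplification rates must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Per-sample latent state planted by the generator."""

    samples: tuple
    cluster: np.ndarray               # in {1..6}
    stratum: np.ndarray               # "BRAF" | "NRAS" | "WT"
    infiltration: pd.DataFrame        # samples x 24 cell types

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.cluster, "stratum": self.stratum},
            index=pd.Index(self.samples, name="sample"),
        )


def synthetic_compendium(n_genes: int = 380) -> SignatureCompendium:
    """A 24-cell-type compendium of ``n_genes`` synthetic marker symbols.

    Gene sets are disjoint across cell types (the post-composite-label state
    of a real compendium).  Genes are spread as evenly as possible.
    """
    if n_genes < len(CELL_TYPES):
        raise ValueError("need at least one gene per cell type")
    per, extra = divmod(n_genes, len(CELL_TYPES))
    classes = {t: ("innate" if t in INNATE_TYPES else "adaptive") for t in CELL_TYPES}
    entries = []
    for i, label in enumerate(CELL_TYPES):
        slug = label.upper().replace(" ", "").replace("+", "")
        count = per + (1 if i < extra else 0)
        entries.extend((f"{slug}.S{j + 1:02d}", label) for j in range(count))
    return SignatureCompendium(entries, classes)


def _keratin_genes(cfg: SyntheticConfig) -> list:
    return [f"KRTB.{j + 1:02d}" for j in range(cfg.keratin_n_genes)]


def _background_genes(cfg: SyntheticConfig) -> list:
    return [f"BG.{j + 1:04d}" for j in range(cfg.n_background_genes)]


def generate_cohort(cfg: SyntheticConfig, comp: SignatureCompendium | None = None):
    """Draw (raw ExpressionMatrix, SyntheticTruth) for one cohort.

    Signature gene g of cell type t in sample s:
        baseline + signature_effect * infiltration[s, t] + N(0, noise_sd)
    Keratin genes gain ``keratin_shift`` in the keratin clusters; pathway
    genes follow baseline + pathway_coupling * T-cell infiltration; background
    genes are baseline plus noise.
    """
    if cfg.n_samples < 12:
        raise ValueError("n_samples must be >= 12 to support clustering")
    comp = comp if comp is not None else synthetic_compendium()
    unknown = [t for t in comp.cell_types if t not in CELL_TYPES]
    if unknown:
        raise ValueError(f"compendium cell types outside the 24 scored types: {unknown}")

    rng = substream(cfg.seed, "expression")
    n = cfg.n_samples
    samples = tuple(f"S{i + 1:04d}" for i in range(n))
    cluster = rng.choice(6, size=n, p=np.asarray(cfg.cluster_proportions)) + 1
    stratum = rng.choice(STRATA, size=n, p=np.asarray(cfg.stratum_proportions))

    type_ix = {t: j for j, t in enumerate(CELL_TYPES)}
    infil = cfg.infiltration_means[cluster - 1, :]  # n x 24, deterministic per cluster
    infil_df = pd.DataFrame(infil, index=list(samples), columns=list(CELL_TYPES))

    gene_sets = comp.gene_sets()
    sig_genes, sig_type_col = [], []
    for t, genes in gene_sets.items():
        sig_genes.extend(genes)
        sig_type_col.extend([type_ix[t]] * len(genes))
    keratin = _keratin_genes(cfg)
    background = _background_genes(cfg)
    all_genes = sig_genes + keratin + list(PATHWAY_GENES) + background

    mean = np.full((len(all_genes), n), cfg.baseline)
    mean[: len(sig_genes), :] += cfg.signature_effect * infil[:, sig_type_col].T
    k0 = len(sig_genes)
    in_keratin_cluster = np.isin(cluster, cfg.keratin_clusters)
    mean[k0 : k0 + len(keratin), :] += cfg.keratin_shift * in_keratin_cluster
    p0 = k0 + len(keratin)
    tcell = infil[:, type_ix["T cells"]]
    mean[p0 : p0 + len(PATHWAY_GENES), :] += cfg.pathway_coupling * tcell

    values = mean
    if cfg.noise_sd > 0:
        values = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    X = ExpressionMatrix(
        pd.DataFrame(values, index=all_genes, columns=list(samples)), state="raw"
    )
    truth = SyntheticTruth(samples=samples, cluster=cluster, stratum=stratum, infiltration=infil_df)
    return X, truth


def generate_molecular_layers(truth: SyntheticTruth, cfg: SyntheticConfig, X: ExpressionMatrix):
    """Draw (methylation beta, mutation flags, CNV calls) for the pathway genes.

    Beta decreases with realized pathway expression (``methyl_coupling`` < 0
    means hypomethylated promoters where the gene is high); mutation flags are
    Bernoulli(mut_rate); CNV calls are +2 with the cluster's amplification
    rate and -2 with ``del_rate`` (amplification wins when both fire).
    """
    rng = substream(cfg.seed, "layers")
    samples = list(truth.samples)
    genes = [g for g in PATHWAY_GENES if g in X.genes]
    if not genes:
        raise ValueError("expression matrix contains no pathway genes")
    expr = X.values.loc[genes, samples]
    centered = expr.sub(expr.mean(axis=1), axis=0)
    beta = 0.5 + cfg.methyl_coupling * centered
    beta = beta + rng.normal(0.0, cfg.methyl_noise_sd, size=beta.shape)
    out_of_range = (beta.to_numpy() < 0) | (beta.to_numpy() > 1)
    if out_of_range.any():
        warnings.warn(
            f"clamping {int(out_of_range.sum())} beta value(s) to [0, 1]", stacklevel=2
        )
        beta = beta.clip(0.0, 1.0)

    mut = pd.DataFrame(
        (rng.random((len(genes), len(samples))) < cfg.mut_rate).astype(int),
        index=genes, columns=samples,
    )
    amp_p = np.asarray(cfg.amp_rate_by_cluster)[truth.cluster - 1]
    amp = rng.random((len(genes), len(samples))) < amp_p[None, :]
    dele = rng.random((len(genes), len(samples))) < cfg.del_rate
    calls = np.where(amp, 2, np.where(dele, -2, 0))
    cnv = pd.DataFrame(calls, index=genes, columns=samples)
    return beta, mut, cnv


def generate_survival(
    truth: SyntheticTruth, score: pd.Series, cfg: SyntheticConfig
) -> pd.DataFrame:
    """Exponential event times with cluster-4 and stratum-specific score hazards.

    hazard_s = baseline_rate * exp(log_hr_cluster4 * 1{cluster=4}
                                   + log_hr_score[stratum] * (score_s - mean score))

    The score enters mean-centered so ``baseline_rate`` stays interpretable as
    the hazard at the cohort-average score; hazard ratios are unchanged.
    Censoring is independent exponential, calibrated so that roughly
    ``censor_rate`` of baseline-hazard samples are censored; ``censor_rate=0``
    disables it.  Returns a clinical table (sample, time, event, cluster_truth,
    stratum, log_hazard).
    """
    if cfg.baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    samples = list(truth.samples)
    score = score.reindex(samples)
    if score.isna().any():
        raise ValueError("score is not aligned to the truth samples")
    rng = substream(cfg.seed, "survival")
    centered = score.to_numpy(dtype=float) - float(score.mean())
    lhr_strat = np.array([cfg.log_hr_score[s] for s in truth.stratum])
    log_hazard = (
        np.log(cfg.baseline_rate)
        + cfg.log_hr_cluster4 * (truth.cluster == 4)
        + lhr_strat * centered
    )
    t_event = rng.exponential(1.0 / np.exp(log_hazard))
    if cfg.censor_rate > 0:
        censor_hazard = cfg.baseline_rate * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_censor = rng.exponential(1.0 / censor_hazard, size=len(samples))
        event = (t_event <= t_censor).astype(int)
        time = np.minimum(t_event, t_censor)
    else:
        event = np.ones(len(samples), dtype=int)
        time = t_event
    return pd.DataFrame(
        {
            "sample": samples,
            "time": time,
            "event": event,
            "cluster_truth": truth.cluster,
            "stratum": truth.stratum,
            "log_hazard": log_hazard,
        }
    )


def write_cohort(outdir, X: ExpressionMatrix, truth: SyntheticTruth, clinical=None,
                 beta=None, mut=None, cnv=None) -> None:
    """Write the generated cohort as plain-text artifacts under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    X.values.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    truth.to_frame().to_csv(out / "truth.csv")
    truth.infiltration.to_csv(out / "infiltration.tsv", sep="\t", index_label="sample")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "samples": list(truth.samples),
                "cluster": truth.cluster.tolist(),
                "stratum": truth.stratum.tolist(),
            },
            fh,
            indent=2,
        )
    if clinical is not None:
        clinical.to_csv(out / "clinical.csv", index=False)
    if beta is not None:
        beta.to_csv(out / "methylation.tsv", sep="\t", index_label="gene")
    if mut is not None:
        mut.to_csv(out / "mutations.tsv", sep="\t", index_label="gene")
    if cnv is not None:
        cnv.to_csv(out / "cnv.tsv", sep="\t", index_label="gene")
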