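"""End-to-end orchestration: discovery and projection runs from one config.

Discovery: standardize the cohort, restrict to the (optionally
lineage-filtered) signature compendium, split train/test, consensus-cluster
the training set, select K, fit centroids, project the held-out test set,
pool labels, cluster genes one-pass, compute cell and pathway scores, and run
enrichment and survival statistics.  Projection: standardize a replication
cohort independently, assign labels by nearest centroid, and recompute scores
and associations.  Every artifact is written as plain text with a manifest
recording the seed, config, and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compendium import (
    FilterConfig,
    SignatureCompendium,
    filter_lineage_expressed,
    read_compendium_gmt,
    read_compendium_tsv,
    read_lineage_profile_tsv,
    write_compendium_tsv,
)
from .consensus import (
    CentroidModel,
    ConsensusParams,
    centroid_fit,
    centroid_predict,
    cluster_genes_onepass,
    consensus_sweep,
)
from .preprocess import (
    ExpressionMatrix,
    log_transform,
    read_expression_tsv,
    split_cohort,
    standardize_genes,
)
from .scoring import CellScoreTable, compute_pathway_scores, score_cells
from .stats import cox_fit, gene_cluster_enrichment, km_logrank, stratified_score_survival
from .synthetic import PATHWAY_GENES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunArtifacts", "run_discovery", "run_projection"]


@dataclass
class PipelineConfig:
    """Run-level configuration (paths + protocol constants)."""

    expression: str = ""
    signatures: str = ""
    clinical: str = ""
    lineage_profiles: tuple = ()
    methylation: str = ""
    mutations: str = ""
    cnv: str = ""
    outdir: str = "melimmune_run"
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    pathway_genes: tuple = PATHWAY_GENES
    train_fraction: float = 2.0 / 3.0
    delta_threshold: float = 0.03
    k_override: int | None = None
    log2_transform: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cons = ConsensusParams(**raw.pop("consensus", {}))
        filt = FilterConfig(**raw.pop("filter", {}))
        for key in ("lineage_profiles", "pathway_genes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(consensus=cons, filter=filt, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["consensus"] = dataclasses.asdict(self.consensus)
        d["filter"] = dataclasses.asdict(self.filter)
        return d


@dataclass
class RunArtifacts:
    """In-memory results of a run; files are listed in the manifest."""

    compendium: SignatureCompendium
    labels: pd.Series
    k_selected: int
    cell_scores: CellScoreTable
    centroids: CentroidModel
    gene_clusters: pd.Series | None = None
    pathway_scores: pd.DataFrame | None = None
    enrichment: object = None
    survival: dict = field(default_factory=dict)
    split: object = None
    consensus: object = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: PipelineConfig, extra: dict) -> dict:
    files = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "melimmune",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "files": files,
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _load_signatures(path: str) -> SignatureCompendium:
    if str(path).endswith(".gmt"):
        return read_compendium_gmt(path)
    return read_compendium_tsv(path)


def _prepare_compendium(cfg: PipelineConfig) -> SignatureCompendium:
    comp = _load_signatures(cfg.signatures)
    if cfg.lineage_profiles:
        profiles = [read_lineage_profile_tsv(p) for p in cfg.lineage_profiles]
        comp = filter_lineage_expressed(comp, profiles, cfg.filter)
    return comp


def _survival_stats(cfg, labels, scores, clinical) -> dict:
    """Log-rank across clusters, Cox for the lowest-immune cluster vs rest,
    and per-stratum score fits when a driver stratum column is present."""
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical.copy()
    common = labels.index.intersection(clin.index)
    clin = clin.loc[common]
    lab = labels.loc[common]
    total = scores.summary["total"].loc[common]
    out: dict = {}
    try:
        lr = km_logrank(clin["time"], clin["event"], lab)
        out["logrank"] = {"chi2": lr.logrank_chi2, "p": lr.logrank_p}
    except ValueError as exc:
        warnings.warn(f"log-rank skipped: {exc}", stacklevel=2)
    # the poor-prognosis candidate: discovered cluster with the lowest mean
    # total immune score (labels themselves are arbitrary integers)
    low_cluster = total.groupby(lab).mean().idxmin()
    indicator = pd.DataFrame({"low_immune_cluster": (lab == low_cluster).astype(int)})
    if indicator["low_immune_cluster"].nunique() > 1:
        cox = cox_fit(clin["time"], clin["event"], indicator)
        row = cox.summary.iloc[0]
        out["low_immune_vs_rest"] = {
            "cluster": int(low_cluster),
            "hr": float(row["hr"]),
            "ci_lower": float(row["ci_lower"]),
            "ci_upper": float(row["ci_upper"]),
            "p": float(row["p"]),
            "converged": cox.converged,
        }
    if "stratum" in clin.columns:
        per = stratified_score_survival(total, clin)
        out["score_by_stratum"] = {
            s: {
                "hr": float(r.summary.loc["score", "hr"]),
                "ci_lower": float(r.summary.loc["score", "ci_lower"]),
                "ci_upper": float(r.summary.loc["score", "ci_upper"]),
                "p": float(r.summary.loc["score", "p"]),
                "converged": r.converged,
            }
            for s, r in per.items()
        }
    return out


def _pathway_layers(cfg: PipelineConfig):
    beta = mut = cnv = None
    if cfg.methylation:
        beta = pd.read_csv(cfg.methylation, sep="\t", index_col=0)
    if cfg.mutations and cfg.cnv:
        mut = pd.read_csv(cfg.mutations, sep="\t", index_col=0)
        cnv = pd.read_csv(cfg.cnv, sep="\t", index_col=0)
    return beta, mut, cnv


def run_discovery(cfg: PipelineConfig) -> RunArtifacts:
    """Full training-set discovery with held-out projection and pooled stats."""
    for name in ("expression", "signatures", "clinical"):
        path = getattr(cfg, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"discovery requires the {name} file (got {path!r})")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    comp = _prepare_compendium(cfg)
    write_compendium_tsv(comp, outdir / "compendium_filtered.tsv")
    X_raw = read_expression_tsv(cfg.expression)
    if cfg.log2_transform:
        X_raw = log_transform(X_raw)
    X = standardize_genes(X_raw).restrict_genes(comp.genes)
    if not len(X.genes):
        raise ValueError("no compendium gene present in the expression matrix")

    split = split_cohort(list(X.samples), fraction=cfg.train_fraction, seed=cfg.seed)
    (outdir / "split.json").write_text(
        json.dumps({"train": list(split.train_ids), "test": list(split.test_ids)}, indent=2)
    )
    X_train = X.restrict_samples(split.train_ids)

    params = dataclasses.replace(cfg.consensus, seed=cfg.seed)
    sweep = consensus_sweep(X_train, params, threshold=cfg.delta_threshold,
                            k_override=cfg.k_override)
    (outdir / "consensus.json").write_text(
        json.dumps(
            {
                "auc": {str(k): v for k, v in sweep.auc.items()},
                "delta": {str(k): v for k, v in sweep.delta.items()},
                "k_selected": sweep.k_selected,
            },
            indent=2,
        )
    )
    for k, res in sweep.by_k.items():
        pd.DataFrame(res.consensus, index=list(res.samples), columns=list(res.samples)).to_csv(
            outdir / f"consensus_K{k}.tsv", sep="\t"
        )
    train_labels = sweep.selected.labels_series()

    centroids = centroid_fit(X_train, train_labels, cohort="training")
    centroids.centroids.to_csv(outdir / "centroids.tsv", sep="\t", index_label="gene")
    (outdir / "centroids.json").write_text(
        json.dumps({"cohort": "training", "n_genes": len(centroids.genes),
                    "clusters": [int(c) for c in centroids.clusters]}, indent=2)
    )
    # test cohort standardized independently before projection
    X_test = standardize_genes(X_raw.restrict_samples(split.test_ids)).restrict_genes(comp.genes)
    test_labels = centroid_predict(X_test, centroids)
    labels = pd.concat([train_labels, test_labels]).loc[list(X.samples)].rename("cluster")
    labels.to_frame().to_csv(outdir / "labels.tsv", sep="\t", index_label="sample")

    gene_clusters = cluster_genes_onepass(X, labels, k_genes=cfg.consensus.k_genes,
                                          seed=cfg.seed)
    gene_clusters.to_frame().to_csv(outdir / "gene_clusters.tsv", sep="\t", index_label="gene")
    enrichment = gene_cluster_enrichment(gene_clusters, comp, alpha=cfg.alpha)
    enrichment.table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    scores = score_cells(X, comp)
    scores.to_frame().to_csv(outdir / "cell_scores.tsv", sep="\t", index_label="sample")
    pathway = None
    if set(cfg.pathway_genes) & set(standardize_genes(X_raw).genes):
        beta, mut, cnv = _pathway_layers(cfg)
        try:
            pathway = compute_pathway_scores(standardize_genes(X_raw), beta, mut, cnv,
                                             gene_set=cfg.pathway_genes)
            pathway.to_csv(outdir / "pathway_scores.tsv", sep="\t", index_label="sample")
        except ValueError as exc:
            warnings.warn(f"pathway scores skipped: {exc}", stacklevel=2)

    clinical = pd.read_csv(cfg.clinical)
    survival = _survival_stats(cfg, labels, scores, clinical)
    (outdir / "survival.json").write_text(json.dumps(survival, indent=2))

    manifest = _write_manifest(outdir, cfg, {"k_selected": sweep.k_selected, "stage": "discovery"})
    return RunArtifacts(
        compendium=comp, labels=labels, k_selected=sweep.k_selected, cell_scores=scores,
        centroids=centroids, gene_clusters=gene_clusters, pathway_scores=pathway,
        enrichment=enrichment, survival=survival, split=split, consensus=sweep,
        manifest=manifest,
    )


def run_projection(cfg: PipelineConfig, centroids: CentroidModel) -> RunArtifacts:
    """Project discovered clusters onto a replication cohort and re-score it."""
    if not cfg.expression or not Path(cfg.expression).exists():
        raise FileNotFoundError(f"projection requires the expression file (got {cfg.expression!r})")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp = _prepare_compendium(cfg) if cfg.signatures else None

    X_raw = read_expression_tsv(cfg.expression)
    if cfg.log2_transform:
        X_raw = log_transform(X_raw)
    X = standardize_genes(X_raw)
    labels = centroid_predict(X.restrict_genes(centroids.genes), centroids,
                              max_gene_loss=0.25)
    labels.to_frame().to_csv(outdir / "labels.tsv", sep="\t", index_label="sample")

    scores = None
    survival: dict = {}
    if comp is not None:
        scores = score_cells(X.restrict_genes(comp.genes), comp)
        scores.to_frame().to_csv(outdir / "cell_scores.tsv", sep="\t", index_label="sample")
    pathway = None
    if set(cfg.pathway_genes) & set(X.genes):
        beta, mut, cnv = _pathway_layers(cfg)
        pathway = compute_pathway_scores(X, beta, mut, cnv, gene_set=cfg.pathway_genes)
        pathway.to_csv(outdir / "pathway_scores.tsv", sep="\t", index_label="sample")
    if cfg.clinical and Path(cfg.clinical).exists() and scores is not None:
        clinical = pd.read_csv(cfg.clinical)
        survival = _survival_stats(cfg, labels, scores, clinical)
        (outdir / "survival.json").write_text(json.dumps(survival, indent=2))

    manifest = _write_manifest(outdir, cfg, {"stage": "projection"})
    return RunArtifacts(
        compendium=comp, labels=labels, k_selected=len(centroids.clusters),
        cell_scores=scores, centroids=centroids, pathway_scores=pathway,
        survival=survival, manifest=manifest,
    )
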