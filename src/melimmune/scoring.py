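"""Immune-cell and Wnt/beta-catenin pathway scores.

Cell-type scores: the mean standardized expression of a cell type's signature
genes per sample, min-max rescaled to [0, 1] within the cohort; the total
immune score sums all 24 cell-type scores, with innate and adaptive subtotals
and the Th1/Th2 ratio.  Pathway scores over the 9 beta-catenin signaling
genes: gx_score = sum of standardized expression, methyl_score = sum(1 - beta)
over promoter methylation, mutCNV_score = sum(I + J) with I the activating-
mutation flag and J in {-1, 0, +1} from deletion/amplification calls, plus
their running combinations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import SignatureCompendium
from .preprocess import ExpressionMatrix
from .synthetic import PATHWAY_GENES

logger = logging.getLogger(__name__)

__all__ = [
    "CellScoreTable",
    "cell_type_score",
    "rescale_unit",
    "aggregate_scores",
    "score_cells",
    "pathway_gx_score",
    "methyl_score",
    "cnv_to_j",
    "mutcnv_score",
    "combine_pathway_scores",
    "compute_pathway_scores",
]


@dataclass
class CellScoreTable:
    """Samples x cell-type scores plus total/innate/adaptive/ratio derivatives."""

    raw: pd.DataFrame        # mean standardized signature-gene expression
    unit: pd.DataFrame       # per-type min-max rescaled to [0, 1]
    summary: pd.DataFrame    # total, innate, adaptive, unclassified, th1_th2_ratio

    @property
    def total(self) -> pd.Series:
        return self.summary["total"]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.unit, self.summary], axis=1)


def cell_type_score(X: ExpressionMatrix, comp: SignatureCompendium) -> pd.DataFrame:
    """raw[s, t] = mean standardized expression of type t's genes in sample s.

    Cell types with no gene present in the matrix are dropped with a warning;
    if no compendium gene at all is present, that is an error.
    """
    if X.state != "standardized":
        raise ValueError("cell scores are computed on standardized expression")
    cols = {}
    missing_types = []
    for t, genes in comp.gene_sets().items():
        present = [g for g in genes if g in X.values.index]
        if not present:
            missing_types.append(t)
            continue
        cols[t] = X.values.loc[present].mean(axis=0)
    if not cols:
        raise ValueError("no compendium gene present in the expression matrix")
    if missing_types:
        warnings.warn(f"cell type(s) with no gene in the matrix dropped: {missing_types}",
                      stacklevel=2)
    raw = pd.DataFrame(cols)
    raw.index.name = "sample"
    return raw


def rescale_unit(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-type min-max rescale across samples to [0, 1].

    A constant column carries no ranking information and is set to 0.5 with a
    warning.
    """
    unit = raw.copy()
    for t in raw.columns:
        lo, hi = raw[t].min(), raw[t].max()
        if hi == lo:
            warnings.warn(f"constant raw score for {t!r}; unit score set to 0.5", stacklevel=2)
            unit[t] = 0.5
        else:
            unit[t] = (raw[t] - lo) / (hi - lo)
    return unit


def aggregate_scores(unit: pd.DataFrame, comp: SignatureCompendium) -> pd.DataFrame:
    """total / innate / adaptive / unclassified sums and the Th1/Th2 ratio.

    Membership comes from the compendium's immunity classes; a membership
    referencing a type absent from ``unit`` is skipped with a warning.
    Th1/Th2 with a zero denominator is +/-inf (flagged) and 0/0 is missing.
    """
    present = list(unit.columns)
    skipped = [t for t in comp.cell_types if t not in present]
    if skipped:
        warnings.warn(f"membership type(s) missing from the score table skipped: {skipped}",
                      stacklevel=2)
    groups = {"innate": [], "adaptive": [], "unclassified": []}
    for t in present:
        groups[comp.immunity_class.get(t, "unclassified")].append(t)
    out = pd.DataFrame(index=unit.index)
    out["total"] = unit.sum(axis=1)
    for name, members in groups.items():
        out[name] = unit[members].sum(axis=1) if members else 0.0
    if "Th1" in unit.columns and "Th2" in unit.columns:
        th1, th2 = unit["Th1"], unit["Th2"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = th1 / th2
        ratio[(th1 == 0) & (th2 == 0)] = np.nan
        if np.isinf(ratio).any():
            # expected for the Th2-minimum sample after min-max rescaling
            logger.info("Th1/Th2 ratio infinite for %d sample(s) with zero Th2 score",
                        int(np.isinf(ratio).sum()))
        out["th1_th2_ratio"] = ratio
    else:
        out["th1_th2_ratio"] = np.nan
    return out


def score_cells(X: ExpressionMatrix, comp: SignatureCompendium) -> CellScoreTable:
    """Full cell-score computation: raw means, unit rescale, aggregates."""
    raw = cell_type_score(X, comp)
    unit = rescale_unit(raw)
    return CellScoreTable(raw=raw, unit=unit, summary=aggregate_scores(unit, comp))


def _present_genes(index, gene_set) -> list:
    return [g for g in gene_set if g in index]


def pathway_gx_score(X: ExpressionMatrix, gene_set=PATHWAY_GENES) -> pd.Series:
    """gx_score = sum of standardized expression over the pathway genes.

    At least 7 of the 9 genes must be present; with missing genes the sum is
    rescaled by len(gene_set)/n_present so scores stay comparable across
    cohorts with different coverage.
    """
    if X.state != "standardized":
        raise ValueError("gx_score is computed on standardized expression")
    present = _present_genes(X.values.index, gene_set)
    min_needed = len(gene_set) - 2
    if len(present) < min_needed:
        raise ValueError(
            f"only {len(present)}/{len(gene_set)} pathway genes present (need >= {min_needed})"
        )
    if len(present) < len(gene_set):
        logger.info("gx_score: missing pathway gene(s) %s; rescaling by %d/%d",
                    sorted(set(gene_set) - set(present)), len(gene_set), len(present))
    scale = len(gene_set) / len(present)
    return (X.values.loc[present].sum(axis=0) * scale).rename("gx_score")


def methyl_score(beta: pd.DataFrame, gene_set=PATHWAY_GENES) -> pd.Series:
    """methyl_score = sum(1 - beta) over the pathway genes' promoters.

    beta is the proportion of methylated CpG sites in [0, 1]; a high score
    therefore means hypomethylated (transcription-permissive) promoters.
    Missing beta entries are imputed with the gene's cohort mean (logged).
    """
    vals = beta.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    present = _present_genes(beta.index, gene_set)
    if not present:
        raise ValueError("no pathway gene present in the methylation table")
    sub = beta.loc[present]
    if sub.isna().any().any():
        logger.info("methyl_score: imputing %d missing beta value(s) with gene means",
                    int(sub.isna().sum().sum()))
        sub = sub.T.fillna(sub.mean(axis=1)).T
    return (1.0 - sub).sum(axis=0).rename("methyl_score")


def cnv_to_j(cnv: pd.DataFrame) -> pd.DataFrame:
    """Map CNV calls (e.g. GISTIC-style {-2, 0, +2}) to J in {-1, 0, +1}."""
    return np.sign(cnv).astype(int)


def mutcnv_score(mut: pd.DataFrame, cnv: pd.DataFrame, gene_set=PATHWAY_GENES) -> pd.Series:
    """mutCNV_score = sum(I + J): activating-mutation flag plus CNV direction."""
    I = mut.reindex(index=list(gene_set)).fillna(0)
    if not I.isin([0, 1]).all().all():
        raise ValueError("mutation flags must be binary")
    J = cnv_to_j(cnv.reindex(index=list(gene_set), columns=I.columns).fillna(0))
    return (I + J).sum(axis=0).rename("mutcnv_score")


def combine_pathway_scores(gx: pd.Series, methyl: pd.Series | None = None,
                           mutcnv: pd.Series | None = None) -> pd.DataFrame:
    """Element-wise running combinations of the per-layer pathway scores."""
    out = pd.DataFrame({"gx_score": gx})
    if methyl is not None:
        out["methyl_score"] = methyl.reindex(gx.index)
        out["gx_plus_methyl"] = out["gx_score"] + out["methyl_score"]
    if mutcnv is not None:
        if methyl is None:
            raise ValueError("mutCNV combination requires the methylation layer")
        out["mutcnv_score"] = mutcnv.reindex(gx.index)
        out["gx_plus_methyl_plus_mutcnv"] = out["gx_plus_methyl"] + out["mutcnv_score"]
    return out


def compute_pathway_scores(
    X: ExpressionMatrix,
    beta: pd.DataFrame | None = None,
    mut: pd.DataFrame | None = None,
    cnv: pd.DataFrame | None = None,
    gene_set=PATHWAY_GENES,
) -> pd.DataFrame:
    """Pathway score table from whichever molecular layers are available."""
    gx = pathway_gx_score(X, gene_set)
    methyl = methyl_score(beta, gene_set) if beta is not None else None
    mc = mutcnv_score(mut, cnv, gene_set) if (mut is not None and cnv is not None) else None
    return combine_pathway_scores(gx, methyl, mc)
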