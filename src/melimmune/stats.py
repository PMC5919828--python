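"""Enrichment, group-comparison, cutpoint, correlation, and survival statistics.

Links discovered clusters and immune scores to gene-cluster composition and
patient outcomes: Fisher exact enrichment with Bonferroni control,
Kruskal-Wallis and ANOVA variance explained, Spearman correlation, an optimal
means-test cutpoint for dichotomizing a biomarker, and Kaplan-Meier/log-rank
and Cox proportional-hazards survival models (optionally per driver-mutation
stratum).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .compendium import SignatureCompendium

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "CutpointResult",
    "SurvivalModelResult",
    "fisher_exact_2x2",
    "gene_cluster_enrichment",
    "bonferroni_threshold",
    "kruskal_wallis",
    "variance_explained",
    "spearman_corr",
    "cutpoint_means_test",
    "km_logrank",
    "cox_fit",
    "stratified_score_survival",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("in", "out")
    col_labels: tuple = ("in", "out")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class EnrichmentResult:
    """Per (gene cluster, cell type) Fisher tests with a Bonferroni family."""

    table: pd.DataFrame      # columns: gene_cluster, cell_type, a, b, c, d, odds_ratio, p, significant
    alpha: float
    m: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.m


@dataclass
class CutpointResult:
    """Optimal dichotomizing cut of a continuous predictor."""

    cut: float
    statistic: float
    n_below: int
    n_above: int
    infinite: bool = False

    @property
    def fraction_above(self) -> float:
        return self.n_above / (self.n_above + self.n_below)


@dataclass
class SurvivalModelResult:
    """Hazard ratios with Wald CIs, or a log-rank comparison, plus metadata."""

    summary: pd.DataFrame    # index: covariate; columns hr, ci_lower, ci_upper, p
    n: int
    n_events: int
    converged: bool = True
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    covariates: tuple = ()


def fisher_exact_2x2(t: ContingencyTable2x2) -> tuple:
    """(sample odds ratio, two-sided exact p).

    p sums hypergeometric probabilities, over tables with the observed
    margins, that do not exceed the observed table's probability (with the
    usual 1e-7 relative slack).  The odds ratio is ad/(bc); infinite when
    bc = 0 with ad > 0, and undefined (nan) when both vanish.
    """
    arr = t.as_array()
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    num, den = t.a * t.d, t.b * t.c
    if den > 0:
        oddsr = num / den
    else:
        oddsr = np.inf if num > 0 else np.nan
    return float(oddsr), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def gene_cluster_enrichment(
    gene_labels: pd.Series, comp: SignatureCompendium, alpha: float = 0.05
) -> EnrichmentResult:
    """Fisher enrichment of each cell type's genes within each gene cluster.

    For each (gene cluster g, cell type t): a 2x2 of cluster membership
    versus cell-type membership over all labeled genes.  The Bonferroni
    family size m is the realized number of (non-empty cluster) x type tests;
    empty clusters are skipped with a warning and m reduced (logged).
    """
    gene_labels = gene_labels.dropna()
    universe = [g for g in gene_labels.index]
    type_sets = {t: set(gs) & set(universe) for t, gs in comp.gene_sets().items()}
    clusters = sorted(gene_labels.unique())
    empty = [c for c in clusters if (gene_labels == c).sum() == 0]
    if empty:
        warnings.warn(f"empty gene cluster(s) skipped: {empty}", stacklevel=2)
        clusters = [c for c in clusters if c not in empty]
    m = len(clusters) * len(type_sets)
    logger.info("gene_cluster_enrichment: m = %d tests (%d clusters x %d types)",
                m, len(clusters), len(type_sets))
    thresh = bonferroni_threshold(alpha, m)
    rows = []
    n_universe = len(universe)
    for c in clusters:
        in_c = set(gene_labels.index[gene_labels == c])
        for t, in_t in type_sets.items():
            a = len(in_c & in_t)
            b = len(in_c) - a
            cc = len(in_t) - a
            d = n_universe - a - b - cc
            oddsr, p = fisher_exact_2x2(ContingencyTable2x2(a, b, cc, d))
            rows.append((c, t, a, b, cc, d, oddsr, p, p < thresh))
    table = pd.DataFrame(
        rows,
        columns=["gene_cluster", "cell_type", "a", "b", "c", "d",
                 "odds_ratio", "p", "significant"],
    )
    return EnrichmentResult(table=table, alpha=alpha, m=m)


def kruskal_wallis(values, groups) -> tuple:
    """(tie-corrected H, chi-square p with groups-1 df) across >= 2 groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    arrays = [values[groups == g] for g in pd.unique(groups)]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need at least 2 non-empty groups")
    if np.all(values == values[0]):
        warnings.warn("all values tied; H = 0, p = 1", stacklevel=2)
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def variance_explained(values, groups) -> float:
    """One-way ANOVA R^2: between-group sum of squares over total."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    if sst == 0:
        return 0.0
    ssb = sum(
        (groups == g).sum() * (values[groups == g].mean() - grand) ** 2
        for g in pd.unique(groups)
    )
    return float(ssb / sst)


def spearman_corr(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def cutpoint_means_test(x, y, min_frac: float = 0.10) -> CutpointResult:
    """Optimal dichotomizing cut of ``x`` by the two-sample means test on ``y``.

    Candidate cuts are the midpoints of consecutive distinct sorted x values
    leaving at least ``min_frac * n`` samples on each side; each is scored by
    the pooled-variance two-sample t statistic for y.  Returns the cut
    maximizing |t| (ties toward the smaller cut).  A zero pooled variance
    flags the statistic as infinite; if no cut discriminates at all (all
    statistics zero) an error is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples for a cutpoint search")
    if len(y) != n:
        raise ValueError("x and y must be the same length")
    if np.unique(x).size < 2:
        raise ValueError("x is constant; no admissible cut")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    min_n = min_frac * n
    best = None  # (|t|, cut, t, n_below, n_above, infinite)
    distinct = np.nonzero(np.diff(xs) > 0)[0]
    for i in distinct:
        n_lo, n_hi = i + 1, n - i - 1
        if n_lo < min_n or n_hi < min_n:
            continue
        cut = (xs[i] + xs[i + 1]) / 2.0
        lo, hi = ys[: i + 1], ys[i + 1 :]
        pooled = ((n_lo - 1) * lo.var(ddof=1) + (n_hi - 1) * hi.var(ddof=1)) / (n - 2)
        diff = hi.mean() - lo.mean()
        if pooled == 0:
            tstat, infinite = (np.inf if diff != 0 else 0.0), diff != 0
        else:
            tstat = diff / np.sqrt(pooled * (1.0 / n_lo + 1.0 / n_hi))
            infinite = False
        key = abs(tstat)
        if best is None or key > best[0]:
            best = (key, cut, tstat, n_lo, n_hi, infinite)
    if best is None:
        raise ValueError("no admissible cut under the minimum group-size constraint")
    if best[0] == 0:
        raise ValueError("no discriminating cut: response does not vary across cuts")
    _, cut, tstat, n_lo, n_hi, infinite = best
    return CutpointResult(cut=float(cut), statistic=float(tstat), n_below=n_lo,
                          n_above=n_hi, infinite=infinite)


def km_logrank(time, event, groups) -> SurvivalModelResult:
    """K-group log-rank test (chi-square) with per-group event counts."""
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    res = multivariate_logrank_test(time, groups, event)
    per_group = pd.DataFrame(
        {
            "n": pd.Series(groups).value_counts().sort_index(),
            "events": pd.Series(event).groupby(pd.Series(groups)).sum(),
        }
    )
    return SurvivalModelResult(
        summary=per_group,
        n=len(time),
        n_events=int(event.sum()),
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def cox_fit(time, event, covariates: pd.DataFrame, strata=None) -> SurvivalModelResult:
    """Cox proportional-hazards fit (Efron tie handling) via partial likelihood.

    Returns per-covariate hazard ratios with 95% Wald CIs and p values.
    Monotone-likelihood / non-convergence (e.g. perfect separation) is
    detected and flagged rather than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    if covariates.isna().any().any() or not np.isfinite(covariates.to_numpy()).all():
        raise ValueError("covariates must be finite")
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    df = covariates.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    if df["_event"].sum() < 1:
        raise ValueError("need at least one event")
    if strata is not None:
        df["_stratum"] = np.asarray(strata)

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                strata="_stratum" if strata is not None else None,
            )
        except ConvergenceError:
            return SurvivalModelResult(
                summary=pd.DataFrame(
                    np.nan, index=covariates.columns,
                    columns=["hr", "ci_lower", "ci_upper", "p"],
                ),
                n=len(df), n_events=int(df["_event"].sum()), converged=False,
                covariates=tuple(covariates.columns),
            )
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                converged = False
                logger.warning("cox_fit: %s", w.message)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return SurvivalModelResult(
        summary=summary,
        n=len(df),
        n_events=int(df["_event"].sum()),
        converged=converged,
        covariates=tuple(covariates.columns),
    )


def stratified_score_survival(
    score: pd.Series, clinical: pd.DataFrame, adjust: pd.DataFrame | None = None
) -> dict:
    """Separate Cox fit of an immune score within each driver-mutation stratum.

    ``clinical`` needs columns time, event, stratum indexed or keyed by
    sample.  Strata without events are skipped with a warning.  Returns
    {stratum: SurvivalModelResult}.
    """
    clin = clinical.copy()
    if "sample" in clin.columns:
        clin = clin.set_index("sample")
    score = score.reindex(clin.index)
    if score.isna().any():
        raise ValueError("score is not aligned to the clinical table")
    out = {}
    for stratum, sub in clin.groupby("stratum"):
        if sub["event"].sum() < 1:
            warnings.warn(f"stratum {stratum!r} has no events; skipped", stacklevel=2)
            continue
        cov = pd.DataFrame({"score": score.loc[sub.index].to_numpy()})
        if adjust is not None:
            for c in adjust.columns:
                cov[c] = adjust.reindex(sub.index)[c].to_numpy()
        out[stratum] = cox_fit(sub["time"], sub["event"], cov)
    return out
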