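"""Shared fixtures: small planted cohorts and brute-force statistical oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import melimmune as m
from melimmune.preprocess import ExpressionMatrix


@pytest.fixture(scope="session")
def compendium():
    return m.synthetic_compendium()


@pytest.fixture(scope="session")
def small_cohort(compendium):
    """High-SNR planted cohort, small enough for per-module tests."""
    cfg = m.SyntheticConfig(n_samples=120, seed=7)
    X, truth = m.generate_cohort(cfg, compendium)
    return cfg, X, truth


@pytest.fixture(scope="session")
def small_standardized(small_cohort, compendium):
    _, X, _ = small_cohort
    return m.standardize_genes(X).restrict_genes(compendium.genes)


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive fixed-margin hypergeometric enumeration.

    Sums, over every table sharing the observed margins, the probabilities
    not exceeding the observed table's (relative slack 1e-7).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = math.comb(r1, k) * math.comb(r2, c1 - k) / denom
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def cutpoint_oracle(x, y, min_frac=0.10):
    """Naive exhaustive cut search scored by scipy's pooled-variance t test."""
    from scipy import stats as sps

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    best = None
    for cut in np.unique((np.sort(x)[:-1] + np.sort(x)[1:]) / 2.0):
        lo, hi = y[x <= cut], y[x > cut]
        if len(lo) < min_frac * n or len(hi) < min_frac * n or len(lo) == 0 or len(hi) == 0:
            continue
        if np.var(np.concatenate([lo - lo.mean(), hi - hi.mean()])) == 0:
            t = np.inf if hi.mean() != lo.mean() else 0.0
        else:
            t = sps.ttest_ind(hi, lo, equal_var=True).statistic
        if best is None or abs(t) > best[0]:
            best = (abs(t), cut)
    return best


def toy_matrix(values, state="raw") -> ExpressionMatrix:
    arr = np.asarray(values, float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        state=state,
    )
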