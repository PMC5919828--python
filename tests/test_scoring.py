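"""Immune-cell score formulas and multi-omic pathway scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import melimmune as m
from melimmune.preprocess import ExpressionMatrix, standardize_genes
from melimmune.scoring import (
    aggregate_scores,
    cell_type_score,
    cnv_to_j,
    combine_pathway_scores,
    methyl_score,
    mutcnv_score,
    pathway_gx_score,
    rescale_unit,
    score_cells,
)
from melimmune.synthetic import CELL_TYPES, PATHWAY_GENES
from melimmune.compendium import load_compendium


def _mini_comp():
    return load_compendium(
        [
            ("a1", "Th1", "adaptive"),
            ("a2", "Th1", "adaptive"),
            ("b1", "NKb", "innate"),
            ("u1", "Other", "unclassified"),
        ]
    )


def _zmat(data: dict, samples) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(data, index=samples).T.astype(float), state="standardized"
    )


def test_cell_type_score_is_mean_of_signature_genes():
    X = _zmat({"a1": [1.0, 0.0], "a2": [0.5, 0.0], "b1": [2.0, 0.0], "u1": [-1.0, 0.0]},
              ["s1", "s2"])
    raw = cell_type_score(X, _mini_comp())
    assert raw.loc["s1", "Th1"] == pytest.approx(0.75)
    assert raw.loc["s1", "NKb"] == pytest.approx(2.0)
    assert (raw.loc["s2"] == 0.0).all()  # all-zero sample scores 0 everywhere


def test_cell_type_score_missing_types_warn_or_error():
    X = _zmat({"a1": [1.0, 2.0]}, ["s1", "s2"])
    with pytest.warns(UserWarning):
        raw = cell_type_score(X, _mini_comp())
    assert list(raw.columns) == ["Th1"]
    empty = _zmat({"zz": [1.0, 2.0]}, ["s1", "s2"])
    with pytest.raises(ValueError):
        cell_type_score(empty, _mini_comp())


def test_rescale_unit_minmax():
    raw = pd.DataFrame({"t": [0.75, 0.25, -0.50]})
    np.testing.assert_allclose(rescale_unit(raw)["t"], [1.0, 0.6, 0.0])
    spanning = pd.DataFrame({"t": [0.0, 0.4, 1.0]})
    np.testing.assert_allclose(rescale_unit(spanning)["t"], [0.0, 0.4, 1.0])


def test_rescale_unit_constant_column():
    with pytest.warns(UserWarning):
        out = rescale_unit(pd.DataFrame({"t": [1.0, 1.0, 1.0]}))
    assert (out["t"] == 0.5).all()


def test_rescale_preserves_ranking():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame({"t": rng.normal(size=50)})
    out = rescale_unit(raw)
    np.testing.assert_array_equal(sps.rankdata(raw["t"]), sps.rankdata(out["t"]))


def test_aggregate_identities_and_ratio(compendium):
    rng = np.random.default_rng(1)
    unit = pd.DataFrame(
        rng.random((10, 24)), columns=list(CELL_TYPES),
        index=[f"s{i}" for i in range(10)],
    )
    agg = aggregate_scores(unit, compendium)
    np.testing.assert_allclose(agg["total"], unit.sum(axis=1))
    np.testing.assert_allclose(
        agg["total"], agg["innate"] + agg["adaptive"] + agg["unclassified"]
    )
    np.testing.assert_allclose(agg["th1_th2_ratio"], unit["Th1"] / unit["Th2"])


def test_aggregate_bounds(compendium):
    ones = pd.DataFrame(1.0, index=["s"], columns=list(CELL_TYPES))
    zeros = pd.DataFrame(0.0, index=["s"], columns=list(CELL_TYPES))
    assert aggregate_scores(ones, compendium).loc["s", "total"] == 24.0
    agg0 = aggregate_scores(zeros, compendium)
    assert (agg0.loc["s", ["total", "innate", "adaptive"]] == 0).all()
    assert np.isnan(agg0.loc["s", "th1_th2_ratio"])  # 0/0 -> missing


def test_th1_th2_ratio_arithmetic(compendium):
    unit = pd.DataFrame(0.5, index=["s"], columns=list(CELL_TYPES))
    unit["Th1"] = 0.6
    unit["Th2"] = 0.3
    assert aggregate_scores(unit, compendium).loc["s", "th1_th2_ratio"] == pytest.approx(2.0)


def test_raw_score_monotone_in_shifted_genes():
    """Raising every Th1 gene in one sample raises only that sample's Th1 score."""
    X = _zmat({"a1": [0.1, 0.2], "a2": [0.0, -0.1], "b1": [0.3, 0.4], "u1": [0.0, 0.0]},
              ["s1", "s2"])
    comp = _mini_comp()
    before = cell_type_score(X, comp)
    bumped = X.values.copy()
    bumped.loc[["a1", "a2"], "s1"] += 0.7
    after = cell_type_score(ExpressionMatrix(bumped, state="standardized"), comp)
    assert after.loc["s1", "Th1"] > before.loc["s1", "Th1"]
    assert after.loc["s2", "Th1"] == before.loc["s2", "Th1"]
    assert after.loc["s1", "NKb"] == before.loc["s1", "NKb"]


def test_raw_scores_track_planted_infiltration(compendium, small_cohort,
                                               small_standardized):
    _, _, truth = small_cohort
    raw = cell_type_score(small_standardized, compendium)
    for t in ("T cells", "Macrophages"):
        rho = sps.spearmanr(raw[t], truth.infiltration[t]).statistic
        assert rho >= 0.8


def test_unit_scores_bounded_with_extremes(compendium, small_standardized):
    table = score_cells(small_standardized, compendium)
    assert (table.unit.to_numpy() >= 0).all() and (table.unit.to_numpy() <= 1).all()
    np.testing.assert_allclose(table.unit.min(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(table.unit.max(axis=0), 1.0, atol=1e-12)
    assert table.summary["total"].between(0, 24).all()


def test_total_score_discriminates_planted_extremes(compendium, small_cohort,
                                                    small_standardized):
    """The total immune score separates the planted high- and low-infiltration
    clusters essentially perfectly (rank AUC >= 0.95)."""
    _, _, truth = small_cohort
    total = score_cells(small_standardized, compendium).summary["total"]
    clusters = pd.Series(truth.cluster, index=list(truth.samples))
    hi = total[clusters == 2].to_numpy()
    lo = total[clusters == 4].to_numpy()
    auc = (hi[:, None] > lo[None, :]).mean()
    assert auc >= 0.95


def _zrow(values):
    return ExpressionMatrix(
        pd.DataFrame(
            np.asarray(values, float)[:, None], index=list(PATHWAY_GENES), columns=["s"]
        ),
        state="standardized",
    )


def test_gx_score_sums_standardized_expression():
    assert pathway_gx_score(_zrow([0.0] * 9))["s"] == 0.0
    assert pathway_gx_score(_zrow([1.0] * 9))["s"] == pytest.approx(9.0)
    assert pathway_gx_score(_zrow([1, -1, 0.5, -0.5, 2, -2, 0, 0, 0]))["s"] == pytest.approx(0.0)


def test_gx_score_missing_gene_rescaling():
    X8 = ExpressionMatrix(
        pd.DataFrame(np.ones((8, 1)), index=list(PATHWAY_GENES[:8]), columns=["s"]),
        state="standardized",
    )
    assert pathway_gx_score(X8)["s"] == pytest.approx(9.0)  # 8 * 9/8
    X6 = ExpressionMatrix(
        pd.DataFrame(np.ones((6, 1)), index=list(PATHWAY_GENES[:6]), columns=["s"]),
        state="standardized",
    )
    with pytest.raises(ValueError):
        pathway_gx_score(X6)


def _beta(value):
    return pd.DataFrame(value, index=list(PATHWAY_GENES), columns=["s"], dtype=float)


def test_methyl_score_endpoints_and_arithmetic():
    assert methyl_score(_beta(1.0))["s"] == pytest.approx(0.0)
    assert methyl_score(_beta(0.0))["s"] == pytest.approx(9.0)
    assert methyl_score(_beta(0.5))["s"] == pytest.approx(4.5)
    with pytest.raises(ValueError):
        methyl_score(_beta(1.5))


def test_methyl_score_imputes_missing_with_gene_mean():
    beta = pd.DataFrame(0.4, index=list(PATHWAY_GENES), columns=["s1", "s2", "s3"])
    beta.loc["CTNNB1", "s1"] = np.nan
    out = methyl_score(beta)
    assert out["s1"] == pytest.approx(out["s2"])


def test_mutcnv_score_formula():
    mut = pd.DataFrame(0, index=list(PATHWAY_GENES), columns=["s"])
    cnv = pd.DataFrame(0, index=list(PATHWAY_GENES), columns=["s"])
    assert mutcnv_score(mut, cnv)["s"] == 0
    mut.loc["MYC"] = 1
    cnv.loc["MYC"] = 2      # amplified and mutated -> +2
    assert mutcnv_score(mut, cnv)["s"] == 2
    mut.loc["MYC"] = 0
    cnv.loc["MYC"] = 0
    cnv.loc["APC"] = -2     # deleted, unmutated -> -1
    assert mutcnv_score(mut, cnv)["s"] == -1


def test_cnv_to_j_sign_mapping():
    calls = pd.DataFrame({"s": [-2, 0, 2]}, index=["a", "b", "c"])
    assert cnv_to_j(calls)["s"].tolist() == [-1, 0, 1]


def test_combine_pathway_scores_elementwise():
    gx = pd.Series({"s": 2.0})
    methyl = pd.Series({"s": 3.0})
    mutcnv = pd.Series({"s": -1.0})
    out = combine_pathway_scores(gx, methyl, mutcnv)
    assert out.loc["s", "gx_plus_methyl"] == 5.0
    assert out.loc["s", "gx_plus_methyl_plus_mutcnv"] == 4.0
    zero = combine_pathway_scores(pd.Series({"s": 0.0}), pd.Series({"s": 0.0}),
                                  pd.Series({"s": 0.0}))
    assert zero.loc["s", "gx_plus_methyl_plus_mutcnv"] == 0.0


def test_pathway_scores_end_to_end(compendium):
    cfg = m.SyntheticConfig(n_samples=80, seed=17)
    X, truth = m.generate_cohort(cfg, compendium)
    beta, mut, cnv = m.generate_molecular_layers(truth, cfg, X)
    table = m.compute_pathway_scores(standardize_genes(X), beta, mut, cnv)
    assert set(table.columns) == {
        "gx_score", "methyl_score", "gx_plus_methyl", "mutcnv_score",
        "gx_plus_methyl_plus_mutcnv",
    }
    assert table["methyl_score"].between(0, 9).all()
    # planted anti-correlation: pathway expression high where T cells low
    total = m.score_cells(standardize_genes(X).restrict_genes(compendium.genes),
                          compendium).summary["total"]
    assert sps.spearmanr(table["gx_score"], total).statistic < -0.5
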