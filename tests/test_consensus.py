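"""Consensus clustering, CDF-area K selection, gene clustering, centroids."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import melimmune as m
from melimmune.consensus import (
    ConsensusParams,
    cdf_and_delta,
    centroid_fit,
    centroid_predict,
    cluster_genes_onepass,
    consensus_cdf_auc,
    consensus_cluster,
    select_k,
)
from melimmune.preprocess import ExpressionMatrix, standardize_genes
from conftest import toy_matrix


def _blocks_matrix(n_per=3, n_genes=10, gap=5.0, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.concatenate(
        [np.full((n_genes, n_per), gap), np.full((n_genes, n_per), -gap)], axis=1
    ) + rng.normal(0, noise, (n_genes, 2 * n_per))
    return standardize_genes(toy_matrix(vals))


def test_two_block_toy_consensus_is_exact():
    X = _blocks_matrix()
    res = consensus_cluster(X, 2, ConsensusParams(reps=50, seed=0))
    assert res.consensus[:3, :3].min() == 1.0
    assert res.consensus[:3, 3:].max() == 0.0
    assert adjusted_rand_score(res.labels, [1, 1, 1, 2, 2, 2]) == 1.0


def test_consensus_matrix_invariants():
    rng = np.random.default_rng(3)
    X = standardize_genes(toy_matrix(rng.normal(size=(20, 15))))
    res = consensus_cluster(X, 3, ConsensusParams(reps=40, seed=1))
    M = res.consensus
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 1.0)
    assert M.min() >= 0.0 and M.max() <= 1.0


def test_no_resampling_limit_matches_single_kmeans():
    """With p_item=p_feature=1 and one repetition the consensus matrix is the
    binary co-membership matrix of a single k-means run."""
    X = _blocks_matrix()
    res = consensus_cluster(X, 2, ConsensusParams(reps=1, p_item=1.0, p_feature=1.0, seed=5))
    assert set(np.unique(res.consensus)) == {0.0, 1.0}
    co = (res.labels[:, None] == res.labels[None, :]).astype(float)
    np.testing.assert_array_equal(res.consensus, co)


def test_planted_three_clusters_recovered():
    rng = np.random.default_rng(4)
    centers = np.array([[4.0], [0.0], [-4.0]])
    truth = np.repeat([0, 1, 2], 4)
    vals = centers[truth].T + rng.normal(0, 1.0, (8, 12))  # gap = 4 SD
    X = standardize_genes(toy_matrix(vals))
    res = consensus_cluster(X, 3, ConsensusParams(reps=500, seed=2))
    assert adjusted_rand_score(truth, res.labels) == 1.0


def test_consensus_deterministic_under_seed():
    X = _blocks_matrix(noise=0.5)
    p = ConsensusParams(reps=25, seed=9)
    r1 = consensus_cluster(X, 2, p)
    r2 = consensus_cluster(X, 2, p)
    np.testing.assert_array_equal(r1.consensus, r2.consensus)
    np.testing.assert_array_equal(r1.labels, r2.labels)


def test_permuting_samples_permutes_consensus_conjugately():
    rng = np.random.default_rng(6)
    X = standardize_genes(toy_matrix(rng.normal(size=(15, 10))))
    res = consensus_cluster(X, 2, ConsensusParams(reps=60, seed=3))
    perm = rng.permutation(10)
    Xp = ExpressionMatrix(X.values.iloc[:, perm], state="standardized")
    resp = consensus_cluster(Xp, 2, ConsensusParams(reps=60, seed=3))
    # the AUC (a function of the entry multiset) is essentially invariant;
    # the matrices are not conjugate bit-for-bit because the resampling
    # stream is positional, so compare distributional summaries
    assert abs(consensus_cdf_auc(res.consensus) - consensus_cdf_auc(resp.consensus)) < 0.15


def test_cdf_auc_toy_values():
    M = np.eye(4)
    M[0, 1] = M[1, 0] = 1.0
    M[2, 3] = M[3, 2] = 1.0
    assert consensus_cdf_auc(M) == pytest.approx(4 / 6)
    assert consensus_cdf_auc(np.ones((4, 4))) == 0.0


def test_cdf_auc_against_quadrature_oracle():
    """The closed-form AUC matches numeric integration of the empirical CDF."""
    rng = np.random.default_rng(7)
    n = 12
    M = np.eye(n)
    iu = np.triu_indices(n, 1)
    vals = rng.random(len(iu[0]))
    M[iu] = vals
    M = np.maximum(M, M.T)
    np.fill_diagonal(M, 1.0)
    grid = np.linspace(0, 1, 10_000, endpoint=False)
    cdf = (vals[None, :] <= grid[:, None]).mean(axis=1)
    quad = cdf.sum() / len(grid)
    assert consensus_cdf_auc(M) == pytest.approx(quad, abs=1e-3)


def test_delta_rule_and_selection():
    delta = {2: 0.5, 3: 0.2, 4: 0.1, 5: 0.02, 6: 0.01}
    assert select_k(delta) == 4
    assert select_k(delta, override=6) == 6
    with pytest.raises(ValueError):
        select_k(delta, override=13)
    with pytest.warns(UserWarning):
        assert select_k({2: 0.001, 3: 0.002}) == 2


def test_cdf_and_delta_requires_consecutive_k():
    M = np.eye(4)
    with pytest.raises(ValueError):
        cdf_and_delta({2: M})
    with pytest.raises(ValueError):
        cdf_and_delta({2: M, 4: M})
    auc, delta = cdf_and_delta({2: M, 3: M})
    assert delta[2] == auc[2]


def test_gene_onepass_separable_blocks():
    """Four duplicated gene blocks each form one gene cluster."""
    rng = np.random.default_rng(8)
    base = rng.normal(size=(4, 20)) * 4
    vals = np.repeat(base, 5, axis=0) + rng.normal(0, 0.1, (20, 20))
    X = standardize_genes(toy_matrix(vals))
    labels = cluster_genes_onepass(X, np.zeros(20, dtype=int), k_genes=4, seed=0)
    truth = np.repeat(np.arange(4), 5)
    assert adjusted_rand_score(truth, labels) == 1.0
    again = cluster_genes_onepass(X, np.zeros(20, dtype=int), k_genes=4, seed=0)
    assert (labels == again).all()


def test_gene_onepass_rejects_k_above_gene_count():
    X = standardize_genes(toy_matrix(np.random.default_rng(0).normal(size=(3, 8))))
    with pytest.raises(ValueError):
        cluster_genes_onepass(X, np.zeros(8, dtype=int), k_genes=4)


def test_gene_onepass_separates_innate_from_adaptive(compendium):
    """When infiltration profiles decouple innate from adaptive cell types,
    their signature genes fall into different gene clusters."""
    infil = np.zeros((6, 24))
    innate = np.array([t in m.compendium.INNATE_TYPES for t in m.synthetic.CELL_TYPES])
    for c in range(6):  # innate high in even clusters, adaptive in odd
        infil[c, :] = np.where(innate, 2.0 * (c % 2), 2.0 * ((c + 1) % 2))
    cfg = m.SyntheticConfig(
        n_samples=100, seed=21, infiltration_means=infil,
        cluster_proportions=(1 / 6,) * 6, n_background_genes=0,
    )
    X, truth = m.generate_cohort(cfg, compendium)
    Z = standardize_genes(X).restrict_genes(compendium.genes)
    labels = cluster_genes_onepass(Z, truth.cluster, k_genes=2, seed=0)
    gene_is_innate = [
        compendium.immunity_class[compendium.labels_of(g)[0]] == "innate" for g in Z.genes
    ]
    assert adjusted_rand_score(gene_is_innate, labels) >= 0.9


def test_centroid_fit_identity_and_symmetry():
    X = toy_matrix([[1.0, -1.0, 2.0], [0.5, -0.5, 1.0]], state="standardized")
    model = centroid_fit(X, [1, 1, 2])
    np.testing.assert_allclose(model.centroids[1], [0.0, 0.0])  # (v, -v) -> zero centroid
    np.testing.assert_allclose(model.centroids[2], [2.0, 1.0])  # singleton -> its profile


def test_centroid_fit_rejects_unlabeled_clusters():
    X = toy_matrix(np.random.default_rng(0).normal(size=(4, 4)), state="standardized")
    model = centroid_fit(X, [1, 1, 2, 2])
    assert model.clusters == [1, 2]


def test_centroid_recovers_generating_profile(compendium):
    """Cluster centroids on raw expression approach the generating means."""
    cfg = m.SyntheticConfig(n_samples=400, seed=15, cluster_proportions=(1 / 6,) * 6)
    X, truth = m.generate_cohort(cfg, compendium)
    genes = list(compendium.genes)
    type_of = {g: compendium.labels_of(g)[0] for g in genes}
    for c in (2, 4):
        members = np.asarray(truth.samples)[truth.cluster == c]
        emp = X.values.loc[genes, members].mean(axis=1)
        expected = np.array(
            [cfg.baseline + cfg.infiltration_means[c - 1, list(m.synthetic.CELL_TYPES).index(type_of[g])]
             for g in genes]
        )
        bound = 5 * cfg.noise_sd / np.sqrt(len(members))
        assert np.abs(emp.to_numpy() - expected).max() < bound


def test_centroid_predict_hand_computed_rank_correlation():
    """x = (2,1,4,3,5) rank-correlates +0.8 with (1..5) and -0.8 with (5..1)."""
    model = m.CentroidModel(
        pd.DataFrame({1: [1.0, 2, 3, 4, 5], 2: [5.0, 4, 3, 2, 1]}, index=list("abcde"))
    )
    X = ExpressionMatrix(
        pd.DataFrame({"x": [2.0, 1, 4, 3, 5]}, index=list("abcde")), state="standardized"
    )
    assert centroid_predict(X, model).tolist() == [1]


def test_centroid_predict_identity_and_errors():
    cents = pd.DataFrame({1: [1.0, 2, 3], 2: [3.0, 2, 1]}, index=list("abc"))
    model = m.CentroidModel(cents)
    X = ExpressionMatrix(cents.rename(columns={1: "s1", 2: "s2"}), state="standardized")
    assert centroid_predict(X, model).tolist() == [1, 2]
    tiny = ExpressionMatrix(
        pd.DataFrame({"s": [1.0, 2]}, index=list("ab")), state="standardized"
    )
    with pytest.raises(ValueError):
        centroid_predict(tiny, model)


def test_centroid_predict_gene_loss_threshold():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(20)]
    model = m.CentroidModel(pd.DataFrame(rng.normal(size=(20, 2)), index=genes, columns=[1, 2]))
    X = ExpressionMatrix(
        pd.DataFrame(rng.normal(size=(10, 3)), index=genes[:10],
                     columns=["a", "b", "c"]),
        state="standardized",
    )
    with pytest.raises(ValueError, match="absent"):
        centroid_predict(X, model)


def test_self_projection_on_separable_data():
    """Refitting centroids on noiseless separable clusters reproduces labels.

    Block profiles vary across genes (mirror-image vectors) so the rank
    correlation against each centroid is informative.
    """
    rng = np.random.default_rng(11)
    v = rng.normal(size=15)
    vals = np.concatenate([np.tile(v[:, None], 5), np.tile(-v[:, None], 5)], axis=1)
    X = standardize_genes(toy_matrix(vals + rng.normal(0, 0.01, vals.shape)))
    labels = np.array([1] * 5 + [2] * 5)
    model = centroid_fit(X, labels)
    assert (centroid_predict(X, model).to_numpy() == labels).all()
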