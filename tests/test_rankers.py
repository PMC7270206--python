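"""Importance rankers against independent oracles and invariance properties."""

import numpy as np
import pytest
from scipy.optimize import minimize

from werfe.dataset import ExpressionDataset
from werfe.errors import ConfigError, DataValidationError
from werfe.rankers import (
    fisher_scores,
    make_ranker,
    relieff_scores,
    rf_importance_scores,
    svm_weight_scores,
)
from werfe.synthetic import SyntheticSpec, generate


def _dataset(matrix, labels, prefix="g"):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionDataset(
        matrix=matrix,
        labels=np.asarray(labels),
        gene_ids=[f"{prefix}{j}" for j in range(matrix.shape[1])],
    )


class TestSvmWeights:
    def test_label_copy_beats_constant_gene(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        matrix = np.column_stack([labels.astype(float), np.full(6, 3.0)])
        scores = svm_weight_scores(_dataset(matrix, labels), standardize=False)
        assert scores.scores[0] > scores.scores[1]
        assert scores.scores[1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicating_samples_is_a_penalty_rescaling(self, planted_factory):
        # duplicating every sample doubles the hinge-loss term, which is
        # exactly equivalent to doubling C: w is identical under C -> C/2,
        # and the ranking of the informative genes is unchanged either way
        data, truth = planted_factory(m=30, n=6, n_informative=2, effect=3.0, seed=1)
        doubled = ExpressionDataset(
            matrix=np.vstack([data.matrix, data.matrix]),
            labels=np.concatenate([data.labels, data.labels]),
            gene_ids=data.gene_ids,
        )
        base = svm_weight_scores(data, C=1.0)
        rescaled = svm_weight_scores(doubled, C=0.5)
        # equal up to the QP solver's stopping tolerance
        np.testing.assert_allclose(base.scores, rescaled.scores, rtol=2e-2)
        same_c = svm_weight_scores(doubled, C=1.0)
        assert set(same_c.ranking()[:2]) == set(base.ranking()[:2]) == set(truth)

    def test_matches_hard_margin_qp_oracle(self):
        # 4-point separable toy; with a huge C the soft margin approaches the
        # hard-margin problem min ||w||^2/2 s.t. y_i (w.x_i + b) >= 1, which
        # we solve here with a general-purpose constrained optimizer.
        X = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 0.0], [4.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        sign = np.where(y == 1, 1.0, -1.0)

        def objective(wb):
            return 0.5 * (wb[0] ** 2 + wb[1] ** 2)

        cons = [
            {"type": "ineq", "fun": (lambda wb, i=i: sign[i] * (X[i] @ wb[:2] + wb[2]) - 1)}
            for i in range(4)
        ]
        sol = minimize(objective, x0=[1.0, 0.0, 0.0], constraints=cons, method="SLSQP")
        assert sol.success
        expected = sol.x[:2] ** 2

        scores = svm_weight_scores(_dataset(X, y), C=1e6, standardize=False)
        np.testing.assert_allclose(scores.scores, expected, rtol=1e-3, atol=1e-8)

    def test_rescaling_invariance_only_with_standardization(self, planted_factory):
        data, _ = planted_factory(m=40, n=5, n_informative=2, effect=2.0, seed=3)
        scale = np.array([1.0, 100.0, 0.01, 5.0, 1.0])
        rescaled = ExpressionDataset(
            matrix=data.matrix * scale, labels=data.labels, gene_ids=data.gene_ids
        )
        on_a = svm_weight_scores(data, standardize=True)
        on_b = svm_weight_scores(rescaled, standardize=True)
        np.testing.assert_allclose(on_a.scores, on_b.scores, rtol=1e-6)
        off_a = svm_weight_scores(data, standardize=False)
        off_b = svm_weight_scores(rescaled, standardize=False)
        assert not np.allclose(off_a.scores, off_b.scores, rtol=1e-3)

    def test_parameter_and_data_errors(self, tiny_data):
        with pytest.raises(ConfigError):
            svm_weight_scores(tiny_data, C=0.0)
        single = np.array([1] * 5 + [0])
        with pytest.raises(DataValidationError):
            svm_weight_scores(_dataset(np.random.default_rng(0).normal(size=(6, 3)), single))


class TestRfImportance:
    def test_permuted_labels_give_no_dominant_gene(self):
        # pure-noise labels: no gene should stand far above the pack
        rng = np.random.default_rng(7)
        matrix = rng.standard_normal((100, 100))
        labels = rng.permutation([0, 1] * 50)
        data = _dataset(matrix, labels)
        mean_scores = np.mean(
            [rf_importance_scores(data, n_trees=200, seed=seed).scores for seed in range(10)],
            axis=0,
        )
        assert mean_scores.max() < 3.0 * np.median(mean_scores)

    def test_planted_gene_tops_ranking(self):
        rng = np.random.default_rng(11)
        labels = np.array([0, 1] * 15)
        matrix = rng.standard_normal((30, 21))
        matrix[:, 7] = labels * 4.0 + rng.standard_normal(30) * 0.2
        scores = rf_importance_scores(_dataset(matrix, labels), n_trees=500, seed=0)
        assert scores.ranking()[0] == "g7"

    def test_deterministic_given_seed(self, tiny_data):
        a = rf_importance_scores(tiny_data, n_trees=50, seed=9).scores
        b = rf_importance_scores(tiny_data, n_trees=50, seed=9).scores
        np.testing.assert_array_equal(a, b)


class TestFisherScores:
    def test_identical_class_means_score_zero(self):
        labels = np.array([0, 0, 1, 1])
        matrix = np.array([[1.0, 0.0], [3.0, 1.0], [1.0, 2.0], [3.0, 3.0]])
        scores = fisher_scores(_dataset(matrix, labels))
        assert scores.scores[0] == pytest.approx(0.0, abs=1e-9)

    def test_perfect_separation_dominates(self):
        rng = np.random.default_rng(2)
        labels = np.array([0, 0, 1, 1])
        matrix = rng.standard_normal((4, 4))
        matrix[:, 2] = labels.astype(float)  # {0,0} vs {1,1}: zero within-variance
        scores = fisher_scores(_dataset(matrix, labels))
        assert scores.ranking()[0] == "g2"

    def test_matches_direct_formula_on_fixture(self):
        rng = np.random.default_rng(5)
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        matrix = rng.standard_normal((8, 5))
        expected = []
        for j in range(5):
            col = matrix[:, j]
            c0, c1 = col[labels == 0], col[labels == 1]
            mu = col.mean()
            between = len(c0) * (c0.mean() - mu) ** 2 + len(c1) * (c1.mean() - mu) ** 2
            within = len(c0) * c0.var() + len(c1) * c1.var()
            expected.append(between / (within + 1e-12))
        scores = fisher_scores(_dataset(matrix, labels))
        np.testing.assert_allclose(scores.scores, expected, rtol=1e-12)

    def test_requires_two_per_class(self):
        with pytest.raises(DataValidationError):
            fisher_scores(_dataset(np.ones((3, 2)), [0, 0, 1]))


class TestRelieff:
    def test_label_copy_is_maximal(self, planted_factory):
        rng = np.random.default_rng(3)
        labels = np.array([0, 1] * 10)
        matrix = rng.standard_normal((20, 4))
        matrix[:, 1] = labels.astype(float)
        scores = relieff_scores(_dataset(matrix, labels), k_neighbors=3)
        assert scores.ranking()[0] == "g1"
        assert scores.scores[1] > 0

    def test_independent_gene_weight_near_zero(self):
        labels = np.array([0, 1] * 100)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            matrix = rng.standard_normal((200, 3))
            matrix[:, 0] = labels + rng.standard_normal(200) * 0.3  # anchor gene
            scores = relieff_scores(_dataset(matrix, labels), k_neighbors=5)
            assert abs(scores.scores[1]) < 0.1
            assert abs(scores.scores[2]) < 0.1

    def test_k1_matches_exhaustive_neighbor_enumeration(self):
        # 6-sample, 2-gene fixture; oracle enumerates the single nearest
        # hit/miss per probe by brute force on [0,1]-scaled features.
        matrix = np.array(
            [[0.0, 5.0], [0.2, 9.0], [0.9, 6.0], [1.0, 8.0], [0.1, 7.0], [0.8, 5.5]]
        )
        labels = np.array([0, 0, 1, 1, 0, 1])
        lo, hi = matrix.min(axis=0), matrix.max(axis=0)
        scaled = (matrix - lo) / (hi - lo)
        w = np.zeros(2)
        for i in range(6):
            dists = np.abs(scaled - scaled[i]).sum(axis=1)
            best_hit, best_miss, dh, dm = None, None, np.inf, np.inf
            for j in range(6):
                if j == i:
                    continue
                if labels[j] == labels[i] and dists[j] < dh:
                    best_hit, dh = j, dists[j]
                if labels[j] != labels[i] and dists[j] < dm:
                    best_miss, dm = j, dists[j]
            w += np.abs(scaled[best_miss] - scaled[i])
            w -= np.abs(scaled[best_hit] - scaled[i])
        expected = w / 6
        scores = relieff_scores(_dataset(matrix, labels), k_neighbors=1)
        np.testing.assert_allclose(scores.scores, expected, rtol=1e-12)

    def test_k_too_large_rejected(self, tiny_data):
        with pytest.raises(DataValidationError):
            relieff_scores(tiny_data, k_neighbors=6)


@pytest.mark.parametrize(
    "ranker_name,params,tol",
    [
        ("svm", {}, dict(rtol=1e-9)),
        # tree randomness depends on column order, so the forest is
        # equivariant only in expectation: generous absolute tolerance
        ("rf", {"n_trees": 800}, dict(atol=0.06)),
        ("fisher", {}, dict(rtol=1e-9)),
        ("relieff", {"k_neighbors": 3}, dict(rtol=1e-9)),
    ],
)
def test_gene_permutation_equivariance(ranker_name, params, tol, planted_factory):
    """Permuting gene columns permutes scores identically."""
    data, _ = planted_factory(m=30, n=8, n_informative=2, effect=2.5, seed=4)
    rng = np.random.default_rng(0)
    perm = rng.permutation(data.n_genes)
    permuted = ExpressionDataset(
        matrix=data.matrix[:, perm],
        labels=data.labels,
        gene_ids=[data.gene_ids[i] for i in perm],
    )
    ranker = make_ranker(ranker_name, **params)
    base = ranker(data, 0)
    after = ranker(permuted, 0)
    np.testing.assert_allclose(np.asarray(base.scores)[perm], after.scores, **tol)


@pytest.mark.parametrize("ranker_name,params", [("fisher", {}), ("relieff", {"k_neighbors": 3})])
def test_sample_order_invariance(ranker_name, params, planted_factory):
    data, _ = planted_factory(m=24, n=6, n_informative=2, effect=2.0, seed=6)
    shuffled = data.take_samples(np.random.default_rng(1).permutation(data.n_samples))
    ranker = make_ranker(ranker_name, **params)
    np.testing.assert_allclose(
        ranker(data, 0).scores, ranker(shuffled, 0).scores, rtol=1e-9
    )
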