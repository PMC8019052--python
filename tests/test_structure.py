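"""Admixture EM, K selection by CV, stock mixtures and exact tests."""

import numpy as np
import pytest
from scipy import stats as sstats
from scipy.special import comb

from charpop import simdata, structure
from tests.test_genomatrix import make_matrix


class TestAdmixtureEm:
    def test_k1_closed_form(self, rng):
        x = rng.binomial(2, 0.3, size=(20, 100)).astype(float)
        res = structure.admixture_em(x, K=1)
        p = x.mean(axis=0) / 2
        np.testing.assert_allclose(res.P[:, 0], p, atol=1e-12)
        # closed-form binomial log-likelihood
        ll = 0.0
        for i in range(20):
            for j in range(100):
                ll += sstats.binom.logpmf(x[i, j], 2, max(p[j], 1e-9))
        assert res.log_likelihood == pytest.approx(ll, rel=1e-9)

    def test_loglik_nondecreasing(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(23, n_loci=200, n=20))
        res = structure.admixture_em(g, K=2, seed=0, n_starts=1, max_iter=100)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs > -1e-6)

    def test_two_demes_recovered(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(29, n_loci=500, n=30))
        res = structure.admixture_em(g, K=2, seed=0, n_starts=4)
        truth = (g.individuals["group"] == "G1").to_numpy()
        hard = res.Q.argmax(axis=1).astype(bool)
        acc = max((hard == truth).mean(), (hard != truth).mean())
        assert acc > 0.95
        np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_panmictic_q_much_less_confident_than_structured(self, two_deme_cfg):
        # maximum-likelihood admixture overfits panmictic data somewhat (no
        # prior shrinks Q), so rows are not fully uniform; but confidence
        # stays far below the essentially-hard assignments of diverged demes
        g0, _ = simdata.simulate_genotypes(two_deme_cfg(31, n_loci=400, fst=0.0, n=30))
        null = structure.admixture_em(g0, K=2, seed=0, n_starts=4)
        g1, _ = simdata.simulate_genotypes(two_deme_cfg(31, n_loci=400, fst=0.2, n=30))
        alt = structure.admixture_em(g1, K=2, seed=0, n_starts=4)
        assert null.Q.max(axis=1).mean() < 0.85
        assert alt.Q.max(axis=1).mean() > 0.95

    def test_missing_genotypes_skipped(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(37, n_loci=300, missing=0.2, n=25))
        res = structure.admixture_em(g, K=2, seed=0, n_starts=2)
        assert np.isfinite(res.log_likelihood)


class TestChooseKCv:
    def test_trivial_single_k(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(41, n_loci=150, n=15))
        k, table = structure.choose_k_cv(g, k_range=[1], seed=0)
        assert k == 1
        assert len(table) == 1

    def test_panmictic_selects_k1(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(43, n_loci=300, fst=0.0, n=30))
        k, _ = structure.choose_k_cv(g, k_range=range(1, 4), seed=0)
        assert k == 1

    def test_two_demes_select_k2(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(47, n_loci=400, n=30))
        k, table = structure.choose_k_cv(g, k_range=range(1, 4), seed=0)
        assert k == 2
        assert table.loc[table["k"] == 2, "cv_error"].iloc[0] < table.loc[
            table["k"] == 1, "cv_error"
        ].iloc[0]


class TestStockMixture:
    def test_planted_stocks_recovered(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(53, n_loci=400, n=30))
        truth = (g.individuals["group"] == "G1").to_numpy()
        res = structure.stock_mixture_em(g, K=2, n_boot=30, seed=0)
        hard = res.assignments.astype(bool)
        acc = max((hard == truth).mean(), (hard != truth).mean())
        assert acc > 0.95
        assert res.bootstrap_support.mean() > 0.9

    def test_degenerate_k_rejected(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(59, n_loci=100, n=5))
        with pytest.raises(ValueError):
            structure.stock_mixture_em(g, K=g.n_individuals)

    def test_contingency_attached(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(61, n_loci=200, n=20))
        sc = np.repeat(["small", "large"], 20)
        res = structure.stock_mixture_em(g, K=2, n_boot=0, seed=0, size_class=sc)
        assert res.contingency.to_numpy().sum() == 40
        assert 0 < res.fisher_p <= 1


class TestFisherExact:
    def test_diagonal_table_enumeration(self):
        p = structure.fisher_exact(np.array([[10, 0], [0, 10]]))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_balanced_table_p_one(self):
        assert structure.fisher_exact(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_degenerate_margin(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert structure.fisher_exact(np.array([[1, 0], [0, 0]])) == 1.0

    def test_matches_scipy_oracle_on_random_tables(self, rng):
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            ours = structure.fisher_exact(t)
            ref = sstats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_2x3_monte_carlo_reasonable(self, rng):
        t = np.array([[12, 3, 1], [2, 10, 9]])
        p = structure.fisher_exact(t, seed=0, n_mc=20000)
        assert p < 0.01  # strongly associated table


class TestFindClustersBic:
    def test_two_blobs_selects_k2(self, rng):
        # realistic dimensionality: the k-means BIC penalty only dominates
        # the within-SS gain of oversplitting in a higher-dimensional score
        # space, as when many PCs are retained
        X = np.vstack(
            [rng.normal(0, 1, (40, 20)), rng.normal(0, 1, (40, 20))]
        )
        X[:40, 0] -= 6
        X[40:, 0] += 6
        labels, curve = structure.find_clusters_bic(X, k_range=range(1, 5), seed=0)
        assert curve.loc[curve["bic"].idxmin(), "k"] == 2
        assert len(np.unique(labels)) == 2

    def test_k1_trivial(self, rng):
        X = rng.normal(size=(30, 2))
        labels, _ = structure.find_clusters_bic(X, k_range=[1], seed=0)
        assert np.all(labels == 0)

    def test_identical_points_flagged(self):
        X = np.zeros((20, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            structure.find_clusters_bic(X, k_range=range(1, 3), seed=0)

    def test_k_exceeding_n_raises(self, rng):
        with pytest.raises(ValueError):
            structure.find_clusters_bic(rng.normal(size=(5, 2)), k_range=[6])


class TestAssignmentAccuracy:
    def test_perfect_correspondence(self):
        post = np.eye(3)[np.repeat([0, 1, 2], 10)]
        labels = np.repeat(["a", "b", "c"], 10)
        assert structure.assignment_accuracy(post, labels) == 100.0

    def test_label_switching_invariance(self, rng):
        post = rng.dirichlet(np.ones(2), size=60)
        labels = rng.choice(["x", "y"], 60)
        a1 = structure.assignment_accuracy(post, labels)
        a2 = structure.assignment_accuracy(post[:, ::-1], labels)
        assert a1 == pytest.approx(a2)

    def test_independent_posteriors_near_chance(self, rng):
        post = rng.dirichlet(np.ones(2), size=400)
        labels = np.repeat(["a", "b"], 200)
        acc = structure.assignment_accuracy(post, labels)
        # Hungarian matching never goes below 50 for balanced binary labels
        assert 50.0 <= acc < 60.0

    def test_mismatched_counts_flagged(self, rng):
        post = rng.dirichlet(np.ones(3), size=30)
        labels = np.repeat(["a", "b"], 15)
        with pytest.warns(UserWarning, match="matching"):
            structure.assignment_accuracy(post, labels)
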