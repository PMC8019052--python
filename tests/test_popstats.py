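"""Reich-Patterson F_ST, diversity statistics and relatedness."""

import numpy as np
import pandas as pd
import pytest

from charpop import popstats as ps
from charpop import simdata
from tests.test_genomatrix import make_matrix


def brute_force_rp(a1, n1, a2, n2):
    """Locus-by-locus pure-python evaluation of the ratio-of-sums estimator."""
    num = den = 0.0
    for x1, m1, x2, m2 in zip(a1, n1, a2, n2):
        if m1 < 2 or m2 < 2:
            continue
        h1 = x1 * (m1 - x1) / (m1 * (m1 - 1))
        h2 = x2 * (m2 - x2) / (m2 * (m2 - 1))
        N = (x1 / m1 - x2 / m2) ** 2 - h1 / m1 - h2 / m2
        num += N
        den += N + h1 + h2
    return num / den


class TestFst:
    def test_fixed_difference_is_one(self):
        res = ps.fst_reich_patterson(([10], [10]), ([0], [10]))
        assert res.estimate == pytest.approx(1.0)

    def test_hand_example(self):
        res = ps.fst_reich_patterson(([4], [10]), ([1], [10]))
        assert res.estimate == pytest.approx(0.0533333 / 0.42, abs=1e-5)
        assert res.estimate == pytest.approx(0.12698, abs=1e-5)

    def test_symmetry_and_allele_flip_invariance(self, rng):
        L = 50
        n1 = np.full(L, 40)
        n2 = np.full(L, 36)
        a1 = rng.integers(0, 41, L)
        a2 = rng.integers(0, 37, L)
        est = ps.fst_reich_patterson((a1, n1), (a2, n2)).estimate
        swapped = ps.fst_reich_patterson((a2, n2), (a1, n1)).estimate
        flipped = ps.fst_reich_patterson((n1 - a1, n1), (n2 - a2, n2)).estimate
        assert est == pytest.approx(swapped, rel=1e-12)
        assert est == pytest.approx(flipped, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            L = 20
            n1 = rng.integers(4, 30, L)
            n2 = rng.integers(4, 30, L)
            a1 = rng.integers(1, n1)
            a2 = rng.integers(1, n2)
            res = ps.fst_reich_patterson((a1, n1), (a2, n2))
            assert res.estimate == pytest.approx(
                brute_force_rp(a1, n1, a2, n2), rel=1e-12
            )

    def test_monomorphic_everything_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = ps.fst_reich_patterson(([0, 0], [10, 10]), ([0, 0], [10, 10]))
        assert res.undefined

    def test_low_count_loci_excluded(self):
        res = ps.fst_reich_patterson(([1, 4], [1, 10]), ([0, 1], [10, 10]))
        assert res.n_excluded == 1
        assert res.n_loci == 1

    def test_panmictic_ci_covers_zero(self, two_deme_cfg):
        # a 95% interval: require coverage of 0 in most of a few replicates
        covered = 0
        for seed in (55, 56, 57):
            g, _ = simdata.simulate_genotypes(two_deme_cfg(seed, n_loci=2000, fst=0.0))
            res = ps.fst_from_matrix(
                g, (g.individuals["group"] == "G1").to_numpy(),
                (g.individuals["group"] == "G2").to_numpy(),
            )
            res = ps.fst_bootstrap_ci(res, n_boot=100, seed=0)
            assert abs(res.estimate) < 0.005  # no divergence planted
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered >= 2


class TestBootstrap:
    def test_identical_ratios_zero_width(self):
        res = ps.FstResult(
            "a", "b", 0.25, np.full(30, 0.1), np.full(30, 0.4), 30, 0
        )
        out = ps.fst_bootstrap_ci(res, n_boot=50, seed=1)
        assert out.ci_low == pytest.approx(out.ci_high) == pytest.approx(0.25)

    def test_single_replicate_flagged(self):
        res = ps.FstResult(
            "a", "b", 0.25, np.array([0.1, 0.2]), np.array([0.4, 0.5]), 2, 0
        )
        with pytest.warns(UserWarning, match="n_boot = 1"):
            out = ps.fst_bootstrap_ci(res, n_boot=1, seed=1)
        assert out.ci_low == pytest.approx(out.ci_high)

    def test_estimate_inside_ci(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(77, n_loci=1500))
        res = ps.fst_from_matrix(
            g, (g.individuals["group"] == "G1").to_numpy(),
            (g.individuals["group"] == "G2").to_numpy(),
        )
        out = ps.fst_bootstrap_ci(res, n_boot=100, seed=3)
        assert out.ci_low <= out.estimate <= out.ci_high


class TestFoldedSfs:
    def test_single_heterozygote_bin_one(self):
        values = np.zeros((5, 3))
        values[0, 1] = 1.0
        spec, n = ps.folded_sfs(make_matrix(values))
        assert n.tolist() == [10, 10, 10]
        assert spec[0] == 2 and spec[1] == 1

    def test_monomorphic_all_in_bin_zero(self):
        spec, _ = ps.folded_sfs(make_matrix(np.zeros((4, 6))))
        assert spec[0] == 6
        assert spec[1:].sum() == 0

    def test_matches_per_site_tally_oracle(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(91, n_loci=400, missing=0.1))
        spec, n_out = ps.folded_sfs(g)
        # brute force per site
        expected = np.zeros_like(spec)
        for j in range(g.n_loci):
            col = g.values[:, j]
            col = col[~np.isnan(col)]
            n = 2 * len(col)
            if n < 2:
                continue
            c = int(min(col.sum(), n - col.sum()))
            expected[c] += 1
        np.testing.assert_array_equal(spec, expected)


class TestWatterson:
    def test_hand_harmonic_example(self):
        # 5 segregating sites among n = 10 alleles at every site, L = 1000
        values = np.zeros((5, 1000))
        for j in range(5):
            values[0, j] = 1.0
        theta = ps.watterson_theta(make_matrix(values))
        a9 = sum(1.0 / i for i in range(1, 10))
        assert a9 == pytest.approx(2.8289683, abs=1e-7)
        assert theta == pytest.approx(5 / (a9 * 1000), rel=1e-9)
        assert theta == pytest.approx(0.0017675, abs=1e-7)

    def test_no_segregation_zero(self):
        assert ps.watterson_theta(make_matrix(np.ones((4, 50)) * 2)) == 0.0

    def test_two_alleles_theta_equals_s_over_l(self):
        values = np.zeros((1, 100))  # one diploid: n = 2 alleles per site
        values[0, :7] = 1.0
        theta = ps.watterson_theta(make_matrix(values))
        assert theta == pytest.approx(7 / 100)

    def test_consistent_with_emitted_spectrum(self, two_deme_cfg):
        g, _ = simdata.simulate_genotypes(two_deme_cfg(13, n_loci=300))
        spec, n_out = ps.folded_sfs(g)
        n = n_out[0]
        assert np.all(n_out == n)  # no missingness in this config
        a = sum(1.0 / i for i in range(1, n))
        theta_from_sfs = spec[1:].sum() / a / len(n_out)
        assert ps.watterson_theta(g) == pytest.approx(theta_from_sfs, rel=1e-12)


class TestHetFis:
    def test_all_heterozygotes_fis_minus_one(self):
        values = np.ones((6, 10))
        out = ps.het_fis(make_matrix(values))
        assert out.ho == pytest.approx(1.0)
        assert out.he == pytest.approx(0.5)
        assert out.fis == pytest.approx(-1.0, abs=1e-9)

    def test_all_homozygotes_fis_one(self):
        values = np.zeros((6, 10))
        values[:3] = 2.0  # p = 0.5, no heterozygotes
        out = ps.het_fis(make_matrix(values))
        assert out.ho == 0.0
        assert out.fis == pytest.approx(1.0)

    def test_hwe_simulation_fis_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 2000)
        values = rng.binomial(2, p, size=(200, 2000)).astype(float)
        out = ps.het_fis(make_matrix(values))
        assert abs(out.fis) < 0.02
        assert out.he_corrected > out.he

    def test_monomorphic_fis_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = ps.het_fis(make_matrix(np.zeros((4, 5))))
        assert out.undefined_fis


class TestRelatedness:
    def test_hand_arithmetic_single_locus(self):
        values = np.array([[0.0], [2.0]])
        out = ps.relatedness_grm(make_matrix(values))
        assert out.normalization == pytest.approx(0.5)
        assert out.values[0, 1] == pytest.approx(-2.0)
        assert np.allclose(out.values, out.values.T)

    def test_unrelated_hwe_mean_near_zero_diag_near_one(self, rng):
        p = rng.uniform(0.1, 0.9, 3000)
        values = rng.binomial(2, p, size=(100, 3000)).astype(float)
        out = ps.relatedness_grm(make_matrix(values))
        assert abs(out.offdiag().mean()) < 0.02
        assert np.mean(np.diag(out.values)) == pytest.approx(1.0, abs=0.05)

    def test_full_siblings_near_half(self, rng):
        p = rng.uniform(0.2, 0.8, 4000)
        # two parents, 20 offspring by Mendelian transmission
        pa = rng.binomial(2, p, size=(2, 4000)).astype(float)

        def gamete(parent):
            return np.where(
                parent == 1, rng.integers(0, 2, parent.shape[0]), parent / 2
            )

        # keep sibs a small fraction of the sample: the allele frequencies
        # used for centring are estimated from the sample itself, and a large
        # related block would bias them toward the parents
        sibs = np.array([gamete(pa[0]) + gamete(pa[1]) for _ in range(10)])
        unrelated = rng.binomial(2, p, size=(190, 4000)).astype(float)
        values = np.vstack([sibs, unrelated])
        out = ps.relatedness_grm(make_matrix(values))
        sib_block = out.values[:10, :10]
        iu = np.triu_indices(10, k=1)
        assert sib_block[iu].mean() == pytest.approx(0.5, abs=0.1)

    def test_mean_imputation_counted(self):
        values = np.array([[0.0, 1.0], [2.0, np.nan], [1.0, 0.0]])
        out = ps.relatedness_grm(make_matrix(values))
        assert out.n_imputed == 1

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError):
            ps.relatedness_grm(make_matrix(np.zeros((3, 4))))


class TestModality:
    def test_single_gaussian_unimodal(self, rng):
        verdict, _ = ps.relatedness_modality(rng.normal(0, 0.05, 500), seed=0)
        assert verdict == "unimodal"

    def test_separated_mixture_bimodal(self, rng):
        vals = np.concatenate([rng.normal(0, 0.03, 250), rng.normal(0.5, 0.03, 250)])
        verdict, delta = ps.relatedness_modality(vals, seed=0)
        assert verdict == "bimodal"
        assert delta >= 3

    def test_constant_values_degenerate_unimodal(self):
        with pytest.warns(UserWarning, match="constant"):
            verdict, _ = ps.relatedness_modality(np.zeros(50))
        assert verdict == "unimodal"


def test_group_fst_exceeds_within_group_fst(small_study):
    """Nested divergence shows up as group >> lake-within-group, as in the
    study's between- vs within-watershed contrast."""
    g = small_study.genotypes
    inds = g.individuals
    between = ps.fst_from_matrix(
        g, (inds["group"] == "Fog").to_numpy(), (inds["group"] == "LTER").to_numpy()
    ).estimate
    within = []
    for l1, l2 in [("Fog1", "Fog3"), ("Fog3", "Fog5"), ("LTER345", "LTER348")]:
        within.append(
            ps.fst_from_matrix(
                g, (inds["lake"] == l1).to_numpy(), (inds["lake"] == l2).to_numpy()
            ).estimate
        )
    assert between > 5 * max(within)
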