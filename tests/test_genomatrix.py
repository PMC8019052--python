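"""VCF I/O, SNP filtering, pairwise-complete covariance and PCA."""

import numpy as np
import pandas as pd
import pytest

from charpop import genomatrix as gm
from charpop.genomatrix import GenotypeMatrix, SNPFilterConfig


def make_matrix(values, chrom=None, pos=None):
    values = np.asarray(values, dtype=float)
    n, L = values.shape
    loci = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr01"] * L,
            "pos": pos if pos is not None else np.arange(1, L + 1) * 1000,
            "ref": ["A"] * L,
            "alt": ["T"] * L,
            "counted_allele": ["T"] * L,
        }
    )
    inds = pd.DataFrame({"id": [f"s{i}" for i in range(n)]})
    return GenotypeMatrix(values, loci, inds)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr01>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


class TestReadVcf:
    def test_hand_written_fixture(self, tmp_path):
        body = (
            "chr01\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr01\t200\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n"
        )
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_HEADER + body)
        g = gm.read_vcf(str(p))
        assert g.values.shape == (3, 2)
        # site 1: ALT freq 0.5 -> ALT counted: 0,1,2
        np.testing.assert_array_equal(g.values[:, 0], [0, 1, 2])
        # site 2: ALT freq 5/6 -> REF becomes the counted (minor) allele
        np.testing.assert_array_equal(g.values[:, 1], [0, 0, 1])
        assert g.loci.loc[1, "counted_allele"] == "G"

    def test_multiallelic_dropped_with_warning(self, tmp_path):
        body = (
            "chr01\t100\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\n"
            "chr01\t200\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/1\n"
        )
        p = tmp_path / "multi.vcf"
        p.write_text(VCF_HEADER + body)
        with pytest.warns(UserWarning, match="multiallelic"):
            g = gm.read_vcf(str(p))
        assert g.n_loci == 1

    def test_all_missing_site_retained(self, tmp_path):
        body = "chr01\t100\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t./.\t./.\n"
        p = tmp_path / "miss.vcf"
        p.write_text(VCF_HEADER + body)
        g = gm.read_vcf(str(p))
        assert g.n_loci == 1
        assert np.isnan(g.values).all()
        assert not g.loci["maf_defined"].iloc[0]

    def test_haploid_genotype_raises(self, tmp_path):
        body = "chr01\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0\t0/1\t1/1\n"
        p = tmp_path / "hap.vcf"
        p.write_text(VCF_HEADER + body)
        with pytest.raises(ValueError, match="diploid"):
            gm.read_vcf(str(p))


class TestFilter:
    def test_toy_six_snp_hand_count(self, rng):
        # 100 fish x 6 SNPs: one at MAF 0.005, one 60% missing, a pair 50 bp
        # apart (second of the pair thinned), two clean -> 3 retained
        n = 100
        values = np.empty((n, 6))
        values[:, 0] = 0.0
        values[0, 0] = 1.0  # MAF = 1/200 = 0.005 < 0.01
        values[:, 1] = rng.integers(0, 3, n)
        values[:60, 1] = np.nan  # 60% missing
        for j in (2, 3, 4, 5):
            values[:, j] = rng.integers(0, 2, n)  # MAF well above 0.01
        g = make_matrix(values, pos=[1000, 2000, 3000, 3050, 5000, 6000])
        out, report = gm.filter_genotypes(g, SNPFilterConfig())
        assert report.n_removed_maf == 1
        assert report.n_removed_missing == 1
        assert report.n_removed_thin == 1
        assert out.n_loci == 3
        np.testing.assert_array_equal(out.loci["pos"].values, [3000, 5000, 6000])

    def test_zero_missing_tolerance_empties_with_status(self):
        values = np.array([[0.0, np.nan], [np.nan, 1.0], [1.0, 0.0]])
        g = make_matrix(values)
        out, report = gm.filter_genotypes(g, SNPFilterConfig(max_missing_frac=0.0))
        assert report.empty
        assert out.n_loci == 0

    def test_thin_zero_disables_thinning(self):
        values = np.tile([0.0, 1.0, 1.0, 2.0], (4, 1)).T
        g = make_matrix(values.T, pos=[100, 110, 120, 130])
        out, report = gm.filter_genotypes(
            g, SNPFilterConfig(thin_bp=0, min_maf=0.0)
        )
        assert report.n_removed_thin == 0

    def test_idempotent(self, small_study):
        g = small_study.genotypes
        once, _ = gm.filter_genotypes(g)
        twice, rep2 = gm.filter_genotypes(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert rep2.n_removed_missing == rep2.n_removed_maf == rep2.n_removed_thin == 0

    def test_thinning_distance_guarantee(self, small_study):
        out, _ = gm.filter_genotypes(small_study.genotypes)
        for _, sub in out.loci.groupby("chrom"):
            assert np.all(np.diff(sub["pos"].values) >= 90)

    def test_high_missing_individuals_dropped(self):
        values = np.ones((4, 10))
        values[3, :9] = np.nan
        values[:, 0] = [0, 1, 2, np.nan]
        g = make_matrix(values)
        out, report = gm.filter_genotypes(
            g, SNPFilterConfig(max_missing_frac=1.0, min_maf=0.0, thin_bp=0,
                               max_ind_missing_frac=0.8)
        )
        assert report.n_removed_individuals == 1
        assert out.n_individuals == 3


class TestCovariance:
    def test_matches_brute_force_without_missing(self, rng):
        values = rng.integers(0, 3, size=(10, 50)).astype(float)
        g = make_matrix(values)
        cov = gm.genotype_covariance(g).covariance
        centred = values - values.mean(axis=0)
        brute = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                brute[i, j] = np.mean(centred[i] * centred[j])
        np.testing.assert_allclose(cov, brute, atol=1e-12)

    def test_identical_individuals_match_diagonal(self, rng):
        v = rng.integers(0, 3, size=(1, 30)).astype(float)
        values = np.vstack([v, v, rng.integers(0, 3, size=(3, 30))])
        cov = gm.genotype_covariance(make_matrix(values)).covariance
        assert cov[0, 1] == pytest.approx(cov[0, 0])

    def test_hand_arithmetic_single_locus_pattern(self):
        # two copies of a (0, 2) locus at p = 0.5: centred is (-1, +1)
        values = np.array([[0.0, 0.0], [2.0, 2.0]])
        cov = gm.genotype_covariance(make_matrix(values)).covariance
        assert cov[0, 1] == pytest.approx(-1.0)
        assert cov[0, 0] == pytest.approx(1.0)

    def test_zero_shared_loci_flagged(self):
        values = np.array(
            [[1.0, np.nan, 0.0], [np.nan, 1.0, np.nan], [0.0, 2.0, 1.0]]
        )
        values[1, 0] = np.nan
        values[1, 2] = np.nan
        values[0, 1] = np.nan
        with pytest.warns(UserWarning, match="share no loci"):
            res = gm.genotype_covariance(make_matrix(values))
        assert res.n_zero_shared_pairs > 0
        assert res.covariance[0, 1] == 0.0


class TestPca:
    def test_eigen_sum_equals_trace(self, rng):
        values = rng.integers(0, 3, size=(20, 100)).astype(float)
        res = gm.pca(gm.genotype_covariance(make_matrix(values)))
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(res.covariance), rel=1e-8
        )
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_rank_one_covariance(self):
        v = np.array([[1.0, -1.0, 2.0]])
        cov = v.T @ v
        res = gm.pca(cov)
        assert (np.abs(res.eigenvalues) > 1e-9).sum() == 1

    def test_identity_covariance_orthonormal(self):
        res = gm.pca(np.eye(4))
        np.testing.assert_allclose(res.eigenvalues, 1.0)
        vecs = res.scores  # sqrt(1) scaling = eigenvectors
        np.testing.assert_allclose(vecs @ vecs.T, np.eye(4), atol=1e-10)

    def test_pc1_separates_diverged_groups(self, two_deme_cfg):
        from charpop import simdata

        g, _ = simdata.simulate_genotypes(two_deme_cfg(31, n_loci=2000))
        res = gm.pca(gm.genotype_covariance(g))
        s1 = res.scores[:, 0]
        grp = g.individuals["group"].to_numpy()
        a, b = s1[grp == "G1"], s1[grp == "G2"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )


class TestPcLengthAssociation:
    def test_perfect_correlation_with_pc1(self, rng):
        values = rng.integers(0, 3, size=(30, 200)).astype(float)
        res = gm.pca(gm.genotype_covariance(make_matrix(values)))
        out = gm.pc_length_association(res, res.scores[:, 0], axes=2)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-20

    def test_planted_dependence_detected(self, rng):
        from charpop import simdata

        cfg = simdata.default_config(
            seed=37, n_loci=1500, fst_between_groups=0.2, fst_within_group=0.0,
            n_sex_loci_xy=0, n_sex_loci_female_only=0,
            lakes=(
                simdata.LakeSpec("A", "G1", 40, ((200, 20, 1.0),)),
                simdata.LakeSpec("B", "G2", 40, ((450, 30, 1.0),)),
            ),
        )
        g, _ = simdata.simulate_genotypes(cfg)
        res = gm.pca(gm.genotype_covariance(g))
        out = gm.pc_length_association(
            res, g.individuals["total_length_mm"].to_numpy(), axes=1
        )
        assert out.loc[0, "p"] < 0.001

    def test_zero_variance_lengths_rejected(self, rng):
        values = rng.integers(0, 3, size=(10, 50)).astype(float)
        res = gm.pca(gm.genotype_covariance(make_matrix(values)))
        with pytest.raises(ValueError):
            gm.pc_length_association(res, np.full(10, 300.0))
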