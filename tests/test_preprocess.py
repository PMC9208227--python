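"""Tests of genotype QC, normalization and transform operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caneqtl import preprocess
from caneqtl.datatypes import ExpressionSet, GenotypeMatrix
from caneqtl.preprocess import (
    filter_genes,
    filter_genotypes,
    genotype_pcs,
    hidden_factors,
    inverse_normal,
    size_factors,
)


def _geno(dosages, pos=None, r2=None):
    dosages = np.asarray(dosages, dtype=float)
    n, k = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(k)],
            "chrom": "chr1",
            "pos": pos if pos is not None else np.arange(1, k + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    if r2 is not None:
        variants["r2"] = r2
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


class TestFilterGenotypes:
    def test_low_maf_variant_removed(self, rng):
        d = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        d[:, 1] = 0.0
        d[0, 1] = 2.0  # MAF 0.005
        out = filter_genotypes(_geno(d), maf_min=0.01)
        assert out.n_variants == 2
        assert "v1" not in set(out.variants["id"])

    def test_sample_with_excess_missingness_removed(self, rng):
        d = rng.binomial(2, 0.3, size=(50, 100)).astype(float)
        d[3, :3] = np.nan  # 3% missing > 2.5%
        out = filter_genotypes(_geno(d), sample_missing_max=0.025)
        assert out.n_samples == 49
        assert "s3" not in out.samples

    def test_clean_data_passes_identity(self, rng):
        d = rng.binomial(2, 0.3, size=(60, 20)).astype(float)
        g = _geno(d, r2=np.full(20, 0.9))
        out = filter_genotypes(g)
        np.testing.assert_array_equal(out.dosages, d)

    def test_low_imputation_r2_removed(self, rng):
        d = rng.binomial(2, 0.3, size=(60, 5)).astype(float)
        out = filter_genotypes(_geno(d, r2=[0.9, 0.2, 0.9, 0.29, 0.31]))
        assert list(out.variants["id"]) == ["v0", "v2", "v4"]

    def test_idempotent(self, rng):
        d = rng.binomial(2, 0.35, size=(80, 40)).astype(float)
        d[rng.uniform(size=d.shape) < 0.01] = np.nan
        once = filter_genotypes(_geno(d))
        twice = filter_genotypes(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        assert list(once.variants["id"]) == list(twice.variants["id"])

    def test_mean_imputation_fills_missing(self, rng):
        # one missing call out of 100 variants keeps the sample (1% < 2.5%)
        d = rng.binomial(2, 0.4, size=(100, 100)).astype(float)
        d[5, 2] = np.nan
        out = filter_genotypes(_geno(d))
        assert out.n_samples == 100
        assert not np.isnan(out.dosages).any()
        expected = np.nanmean(d[:, 2])
        assert out.dosages[5, 2] == pytest.approx(expected)


class TestGenotypePCs:
    def test_two_subpopulations_separate_on_pc1(self, rng):
        from sklearn.metrics import silhouette_score

        n, k = 120, 400
        f1 = rng.uniform(0.05, 0.5, k)
        shift = rng.choice([-0.3, 0.3], k)
        f2 = np.clip(f1 + shift, 0.02, 0.98)
        pop = np.repeat([0, 1], n // 2)
        d = np.where(pop[:, None] == 0,
                     rng.binomial(2, f1, (n, k)),
                     rng.binomial(2, f2, (n, k))).astype(float)
        pcs = genotype_pcs(_geno(d), 2)
        score = silhouette_score(pcs[["PC1"]].to_numpy(), pop)
        assert score > 0.8

    def test_rank_one_matrix_pc1_explains_all_variance(self):
        base = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        d = np.column_stack([base, base, 2 - base])
        pcs = genotype_pcs(_geno(d), 1)
        X = (d - d.mean(0)) / d.std(0)
        total = (X**2).sum()
        assert (pcs["PC1"] ** 2).sum() / total > 0.999

    def test_repeated_call_identical_and_orthogonal(self, rng):
        d = rng.binomial(2, 0.3, size=(50, 80)).astype(float)
        a = genotype_pcs(_geno(d), 4)
        b = genotype_pcs(_geno(d), 4)
        pd.testing.assert_frame_equal(a, b)
        gram = a.to_numpy().T @ a.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_invalid_k(self, rng):
        d = rng.binomial(2, 0.3, size=(20, 30)).astype(float)
        with pytest.raises(ValueError):
            genotype_pcs(_geno(d), 0)
        with pytest.raises(ValueError):
            genotype_pcs(_geno(d), 20)


class TestSizeFactors:
    def test_hand_computed_toy_matrix(self):
        counts = pd.DataFrame([[10, 20, 10], [100, 200, 100]], columns=list("ABC"))
        sf = size_factors(counts)
        np.testing.assert_allclose(sf / sf["A"], [1.0, 2.0, 1.0])

    def test_doubling_one_sample_doubles_its_relative_factor(self, rng):
        """Scaling one sample by c rescales every geometric mean by c^(1/n),
        so the equivariance is exact on factor *ratios*: B/A doubles while
        the untouched samples keep their relative factors."""
        counts = pd.DataFrame(rng.poisson(50, size=(200, 4)) + 1,
                              columns=list("ABCD"))
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled["B"] = counts["B"] * 2
        sf2 = size_factors(scaled)
        assert sf2["B"] / sf2["A"] == pytest.approx(2 * sf["B"] / sf["A"])
        for s in "CD":
            assert sf2[s] / sf2["A"] == pytest.approx(sf[s] / sf["A"])

    def test_two_sample_doubling_factor_ratio_exact(self):
        counts = pd.DataFrame({"A": [10, 30, 7], "B": [20, 60, 14]})
        sf = size_factors(counts)
        assert sf["B"] / sf["A"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        col = pd.Series([5, 50, 500])
        counts = pd.DataFrame({"A": col, "B": col, "C": col})
        sf = size_factors(counts)
        assert sf.nunique() == 1

    def test_no_all_positive_gene_fails(self):
        counts = pd.DataFrame([[0, 5], [5, 0]], columns=list("AB"))
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


def _exprset(counts, tpm=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(len(counts))]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    if tpm is None:
        tpm = counts / counts.sum(axis=0) * 1e6
    else:
        tpm = pd.DataFrame(tpm, index=counts.index, columns=counts.columns)
    genes = pd.DataFrame(
        {"id": counts.index, "chrom": "chr1",
         "start": np.arange(len(counts)) * 1000 + 1,
         "end": np.arange(len(counts)) * 1000 + 500,
         "strand": "+"},
        index=counts.index,
    )
    return ExpressionSet(counts=counts.astype(int), tpm=tpm, genes=genes)


class TestFilterGenes:
    def test_inclusive_boundary_kept(self):
        n = 10
        counts = np.full((2, n), 100)
        tpm = np.full((2, n), 50.0)
        counts[1] = 0
        counts[1, :2] = 6  # exactly 6 reads in exactly 20% of samples
        tpm[1] = 0.0
        tpm[1, :2] = 0.1  # exactly 0.1 TPM
        e = _exprset(counts, tpm)
        kept = filter_genes(e, 0.1, 6, 0.2)
        assert kept.gene_ids == ["g0", "g1"]

    def test_all_zero_gene_removed(self):
        counts = np.array([[50] * 10, [0] * 10])
        e = _exprset(counts)
        assert filter_genes(e).gene_ids == ["g0"]

    def test_fraction_below_threshold_removed(self):
        counts = np.full((2, 10), 100)
        tpm = np.full((2, 10), 50.0)
        counts[1] = 0
        counts[1, 0] = 100  # passes in 1/10 = 0.1 < 0.2
        tpm[1] = 0.0
        tpm[1, 0] = 50.0
        e = _exprset(counts, tpm)
        assert filter_genes(e, 0.1, 6, 0.2).gene_ids == ["g0"]


class TestExpressionOutliers:
    def test_homogeneous_cohort_rarely_flags(self, rng):
        counts = rng.poisson(100, size=(60, 80)) + 1
        e = _exprset(counts)
        preprocess.normalize_expression(e)
        flagged = preprocess.expression_outliers(e, n_pcs=6, sd_cut=3.0)
        # under approximate normality each sample trips with prob ~6*0.0027
        assert len(flagged) <= 5

    def test_constructed_outlier_flagged(self, rng):
        counts = rng.poisson(100, size=(120, 40)) + 1
        e = _exprset(counts)
        preprocess.normalize_expression(e)
        # corrupt one sample's *normalized* profile directly (bypassing
        # size-factor correction) with a wild multiplicative distortion
        bad = e.normalized.columns[7]
        e.normalized[bad] = e.normalized[bad] * rng.uniform(0.05, 20.0, size=120)
        flagged = preprocess.expression_outliers(e, n_pcs=6, sd_cut=3.0)
        assert bad in flagged

    def test_infinite_cut_flags_nothing(self, rng):
        counts = rng.poisson(80, size=(30, 25)) + 1
        e = _exprset(counts)
        preprocess.normalize_expression(e)
        assert preprocess.expression_outliers(e, 6, np.inf) == []


class TestHiddenFactors:
    def test_recovers_strong_planted_factors(self, rng):
        n, g, k = 100, 300, 3
        F = rng.normal(size=(k, n))
        L = rng.normal(scale=2.0, size=(g, k))
        X = np.exp(0.05 * (L @ F) + rng.normal(scale=0.02, size=(g, n)) + 5)
        counts = rng.poisson(X) + 1
        e = _exprset(counts)
        preprocess.normalize_expression(e)
        est = hidden_factors(e, k).to_numpy()
        # canonical correlation between estimated and true factor spaces
        qe, _ = np.linalg.qr(est - est.mean(0))
        qt, _ = np.linalg.qr(F.T - F.T.mean(0))
        sv = np.linalg.svd(qe.T @ qt, compute_uv=False)
        assert sv.min() > 0.9

    def test_pure_noise_shares_are_flat(self, rng):
        counts = rng.poisson(200, size=(400, 80)) + 1
        e = _exprset(counts)
        preprocess.normalize_expression(e)
        est = hidden_factors(e, 5)
        var = est.var(axis=0).to_numpy()
        assert var.max() / var.min() < 3.0  # Marchenko-Pastur-scale spread

    def test_zero_k_rejected(self, rng):
        counts = rng.poisson(50, size=(20, 10)) + 1
        e = _exprset(counts)
        preprocess.normalize_expression(e)
        with pytest.raises(ValueError):
            hidden_factors(e, 0)


class TestInverseNormal:
    def test_three_point_example(self):
        got = inverse_normal([5.0, 1.0, 9.0])
        np.testing.assert_allclose(got, [0.0, -0.8694238, 0.8694238], atol=1e-6)

    @given(st.lists(st.integers(-10**6, 10**6), min_size=5, max_size=60, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, xs):
        x = np.array(xs, dtype=float)
        np.testing.assert_allclose(inverse_normal(x), inverse_normal(np.exp(x / 1e6) * 3 + 7))

    def test_antisymmetry_without_ties(self, rng):
        x = rng.normal(size=51)
        np.testing.assert_allclose(inverse_normal(-x), -inverse_normal(x), atol=1e-12)

    def test_output_variance_near_one(self, rng):
        x = rng.uniform(size=1001)
        v = inverse_normal(x).var(ddof=1)
        assert 0.9 < v < 1.1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal([2.0, 2.0, 2.0])


def test_build_covariates_alignment(prepared_cohort):
    c, geno, expr, covars = prepared_cohort
    assert list(covars.index) == expr.samples
    assert not covars.isna().any().any()
    assert {"PC1", "HF1", "sex"} <= set(covars.columns)
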