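"""Tests of the cis mapping machinery: windows, scans, permutations, q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from caneqtl import cis
from caneqtl.cis import (
    allelic_fold_change,
    beta_adjusted_p,
    call_egenes,
    cis_window,
    fit_beta,
    mac_filter,
    nominal_scan,
    permutation_pass,
    residualize,
    somqtl_test,
    storey_qvalues,
)


def _variants(positions, chrom="chr1"):
    return pd.DataFrame(
        {"id": [f"v{i}" for i in range(len(positions))], "chrom": chrom,
         "pos": positions, "ref": "A", "alt": "G"}
    )


class TestCisWindow:
    gene = pd.Series({"id": "g", "chrom": "chr1", "start": 2_000_000,
                      "end": 2_010_000, "strand": "+"})

    def test_exact_boundary_included(self):
        v = _variants([1_000_000, 999_999, 3_010_000, 3_010_001])
        idx = cis_window(self.gene, v, 1_000_000)
        assert list(idx) == [0, 2]

    def test_zero_window_gene_body_only(self):
        v = _variants([1_999_999, 2_000_000, 2_005_000, 2_010_000, 2_010_001])
        idx = cis_window(self.gene, v, 0)
        assert list(idx) == [1, 2, 3]

    def test_other_chromosome_excluded(self):
        v = _variants([2_000_000], chrom="chr2")
        assert cis_window(self.gene, v).size == 0


class TestMacFilter:
    def test_three_het_carriers_removed_five_kept(self):
        d = np.zeros((200, 2))
        d[:3, 0] = 1.0
        d[:5, 1] = 1.0
        assert list(mac_filter(d, 5)) == [1]

    def test_monomorphic_removed(self):
        d = np.zeros((50, 1))
        assert mac_filter(d, 1).size == 0

    def test_rounding_to_hard_calls(self):
        d = np.full((100, 1), 0.04)  # rounds to 0 everywhere
        assert mac_filter(d, 1).size == 0


class TestNominalScan:
    def test_slope_recovery(self, rng):
        n = 500
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * g + rng.normal(size=n)
        res = nominal_scan(y, g[:, None])
        assert res["slope"][0] == pytest.approx(0.5, abs=0.1)
        assert res["p"][0] < 1e-10

    def test_null_p_uniform(self, rng):
        n, reps = 200, 10_000
        Y = rng.normal(size=(reps, n))
        G = rng.binomial(2, 0.3, size=(reps, n)).astype(float)
        Yc = Y - Y.mean(1, keepdims=True)
        Gc = G - G.mean(1, keepdims=True)
        r = (Yc * Gc).sum(1) / np.sqrt((Yc**2).sum(1) * (Gc**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * st.t.sf(np.abs(t), n - 2)
        # same statistic path as nominal_scan; spot-check agreement then KS
        spot = nominal_scan(Y[0], G[0][:, None])
        assert spot["p"][0] == pytest.approx(p[0])
        assert st.kstest(p, "uniform").pvalue > 0.01

    def test_perfect_fit_underflows(self, rng):
        g = rng.binomial(2, 0.5, 50).astype(float)
        res = nominal_scan(g.copy(), g[:, None])
        assert res["p"][0] <= 1e-300
        assert res["slope"][0] == pytest.approx(1.0)

    def test_zero_variance_variant_rejected(self, rng):
        y = rng.normal(size=30)
        with pytest.raises(ValueError):
            nominal_scan(y, np.ones((30, 1)))


class TestResidualize:
    def test_orthogonal_covariates_leave_ranks(self, rng):
        n = 101
        y = rng.normal(size=n)
        cov = pd.DataFrame({"c1": np.zeros(n)})  # constant -> dropped? it's in covars
        # orthogonal covariate: independent noise, near-zero correlation effect
        cov = pd.DataFrame({"c1": rng.normal(size=n)})
        out = residualize(y, cov)
        # residualizing on near-orthogonal covariate barely changes ranks
        rho = st.spearmanr(out, y).statistic
        assert rho > 0.95

    def test_injected_somatic_shift_removed(self, rng):
        n = 300
        cna = np.zeros(n)
        cna[:30] = 1.0
        y = rng.normal(size=n) + 2.0 * cna
        out = residualize(y, None, (cna, np.zeros(n)))
        t = st.ttest_ind(out[:30], out[30:]).statistic
        assert abs(t) < 2.5

    def test_perfect_fit_degenerates(self, rng):
        n = 50
        c = rng.normal(size=n)
        cov = pd.DataFrame({"c1": c})
        with pytest.raises(ValueError):
            residualize(c.copy(), cov)


class TestPermutationPass:
    def test_null_beta_shapes_match_min_of_uniforms(self, rng):
        """With k independent null variants the minimum p is ~ Beta(1, k)."""
        n, k = 150, 10
        G = rng.normal(size=(n, k))  # independent -> exact Beta(1, k) regime
        y = rng.normal(size=n)
        res = permutation_pass(y, G, 10_000, 10_000, rng=rng)
        assert 0.8 < res.beta_shape1 < 1.2
        assert 8 < res.beta_shape2 < 13

    def test_closed_form_adjusted_p(self):
        assert beta_adjusted_p(0.001, 1, 10) == pytest.approx(1 - 0.999**10)

    def test_strong_effect_extrapolates_below_resolution(self, rng):
        n = 200
        G = rng.binomial(2, 0.3, size=(n, 40)).astype(float)
        y = np.sqrt(0.25) * (G[:, 0] - G[:, 0].mean()) / G[:, 0].std() + rng.normal(size=n)
        res = permutation_pass(y, G, 100, 1000, rng=rng)
        assert res.adjusted_p < 1.0 / 1001
        assert res.adjusted_p > 0

    def test_reproducible_given_seed(self, rng):
        n = 100
        G = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
        y = rng.normal(size=n)
        a = permutation_pass(y, G, 500, 1000, rng=123)
        b = permutation_pass(y, G, 500, 1000, rng=123)
        assert a.adjusted_p == b.adjusted_p
        assert a.empirical_p == b.empirical_p
        np.testing.assert_array_equal(a.perm_minima, b.perm_minima)

    def test_adaptive_stop_on_null(self, rng):
        n = 100
        G = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
        y = rng.normal(size=n)
        res = permutation_pass(y, G, 300, 10_000, rng=rng)
        assert res.n_permutations == 300  # null gene stops early

    def test_empirical_estimator_never_zero(self, rng):
        n = 120
        G = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        y = G[:, 0] + 0.1 * rng.normal(size=n)
        res = permutation_pass(y, G, 100, 200, rng=rng)
        assert res.empirical_p >= 1.0 / (1.0 + res.n_permutations)


class TestFitBeta:
    def test_recovers_known_shapes(self, rng):
        x = rng.beta(1.0, 25.0, size=20_000)
        a, b = fit_beta(x)
        assert a == pytest.approx(1.0, abs=0.1)
        assert b == pytest.approx(25.0, rel=0.1)

    def test_mle_at_least_as_good_as_moments(self, rng):
        x = rng.beta(0.8, 12.0, size=5_000)
        a, b = fit_beta(x)
        m, v = x.mean(), x.var()
        common = m * (1 - m) / v - 1
        am, bm = m * common, (1 - m) * common
        ll = lambda a_, b_: np.sum(st.beta.logpdf(np.clip(x, 1e-12, 1 - 1e-12), a_, b_))
        assert ll(a, b) >= ll(am, bm) - 1e-6


class TestStoreyQ:
    def test_uniform_p_pi0_near_one(self, rng):
        p = rng.uniform(size=5000)
        q = storey_qvalues(p)
        # with pi0 ~ 1 the smallest q is roughly m*p_min/1 ~ U; no explosion of calls
        assert (q <= 0.05).sum() <= 10

    def test_hand_bh_example_with_pi0_one(self):
        q = storey_qvalues(np.array([0.001, 0.5, 0.9]), pi0=1.0)
        np.testing.assert_allclose(q, [0.003, 0.75, 0.9])

    def test_equals_bh_when_pi0_forced(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500) ** 2
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_identical_ps_get_identical_qs(self):
        q = storey_qvalues(np.array([0.2, 0.2, 0.2, 0.9]))
        assert q[0] == q[1] == q[2]

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=2000)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0, 0.5]))


class TestCallEgenes:
    def test_empty_and_full(self):
        assert call_egenes(pd.DataFrame(), 0.05) == set()
        df = pd.DataFrame({"gene_id": ["a", "b"], "q_value": [0.2, 0.9]})
        assert call_egenes(df, 1.0) == {"a", "b"}
        assert call_egenes(df, 0.05) == set()


class TestSomQtl:
    def test_injected_amp_effect_detected(self, rng):
        n, g = 300, 40
        samples = [f"s{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(g)]
        expr = pd.DataFrame(rng.normal(size=(g, n)), index=genes, columns=samples)
        cna = pd.DataFrame(0, index=genes, columns=samples)
        mut = pd.DataFrame(0, index=genes, columns=samples)
        carriers = rng.choice(n, 30, replace=False)
        cna.iloc[0, carriers] = 1
        expr.iloc[0, carriers] += 1.0
        from caneqtl.datatypes import SomaticTable

        res = somqtl_test(expr, SomaticTable(cna, mut), None)
        hit = res[(res["gene_id"] == "g0") & (res["predictor"] == "cna")]
        assert hit["p"].iloc[0] < 1e-4
        assert hit["coefficient"].iloc[0] == pytest.approx(1.0, abs=0.4)

    def test_somatically_quiet_gene_skipped(self, rng):
        n = 50
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(rng.normal(size=(2, n)), index=["g0", "g1"], columns=samples)
        cna = pd.DataFrame(0, index=["g0", "g1"], columns=samples)
        mut = pd.DataFrame(0, index=["g0", "g1"], columns=samples)
        cna.iloc[1, :5] = 1
        from caneqtl.datatypes import SomaticTable

        res = somqtl_test(expr, SomaticTable(cna, mut), None)
        assert set(res["gene_id"]) == {"g1"}

    def test_null_p_uniform(self, rng):
        n, g = 150, 120
        samples = [f"s{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(g)]
        expr = pd.DataFrame(rng.normal(size=(g, n)), index=genes, columns=samples)
        cna = pd.DataFrame(rng.choice([0, 1], p=[0.8, 0.2], size=(g, n)),
                           index=genes, columns=samples)
        mut = pd.DataFrame(0, index=genes, columns=samples)
        from caneqtl.datatypes import SomaticTable

        res = somqtl_test(expr, SomaticTable(cna, mut), None)
        assert st.kstest(res["p"], "uniform").pvalue > 0.01


class TestAllelicFoldChange:
    def test_closed_form(self, rng):
        d = rng.binomial(2, 0.5, 400).astype(float)
        e = 10.0 + 5.0 * d  # b0=10, b1=5 -> log2(20/10) = 1
        assert allelic_fold_change(e, d) == pytest.approx(1.0, abs=1e-9)

    def test_zero_slope_zero_afc(self, rng):
        d = rng.binomial(2, 0.5, 200).astype(float)
        e = np.full(200, 7.0)
        assert allelic_fold_change(e, d) == pytest.approx(0.0, abs=1e-9)

    def test_simulated_twofold_allele(self, rng):
        n = 500
        h1 = rng.binomial(1, 0.5, n)
        h2 = rng.binomial(1, 0.5, n)
        d = (h1 + h2).astype(float)
        # each alt haplotype doubles its output: ref allele emits 1, alt emits 2
        e = ((2 - d) * 1.0 + d * 2.0) * rng.lognormal(0, 0.1, n)
        assert allelic_fold_change(e, d) == pytest.approx(1.0, abs=0.1)

    def test_negative_baseline_flagged(self):
        d = np.array([0.0, 0, 0, 1, 1, 2, 2, 2])
        e = np.array([0.0, 0, 0, 0, 0, 10, 10, 10])  # b0 < 0 after fit
        assert np.isnan(allelic_fold_change(e, d))


def test_map_cis_recovers_planted_effects(prepared_cohort):
    c, geno, expr, covars = prepared_cohort
    res = cis.map_cis(geno, expr, c.somatic, covars, seed=11,
                      n_perm_min=300, n_perm_max=2000)
    assert len(res) == len(expr.gene_ids)
    truth = c.truth.effect_genes() & set(expr.gene_ids)
    got = res.set_index("gene_id")
    # planted effects should rank far better than null genes on adjusted p
    eff_med = got.loc[sorted(truth), "adjusted_p"].median()
    null_med = got.loc[~got.index.isin(truth), "adjusted_p"].median()
    assert eff_med < 0.05 < null_med


def test_lead_tie_break_is_positional():
    """Ties on p resolve to the smaller genomic position, not array index."""
    p = np.array([0.5, 0.01, 0.01, 0.3])
    pos = np.array([100, 900, 200, 50])
    assert cis.lead_index(p, pos) == 2
    # permuting column order with positions attached leaves the winner fixed
    order = np.array([3, 1, 0, 2])
    assert pos[order][cis.lead_index(p[order], pos[order])] == 200
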