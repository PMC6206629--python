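import math

import numpy as np
import pytest
from scipy import stats

from tadip import (
    WeightConfig,
    beta_weights,
    burden_test,
    design_matrix_V,
    null_p0,
    quadform_pvalue,
    vct_test,
    wald_test,
)
from tadip.hypothesis_tests import _liu_pvalue

from conftest import make_table

UNIFORM = WeightConfig(a1=1.0, a2=1.0)


class TestNullP0:
    def test_single_genome_closed_form(self):
        t = make_table([("r1", "gA", 9, 10), ("r2", "gA", 8, 10)])
        p0, E = null_p0(t)
        assert p0 == pytest.approx(0.15, abs=1e-9)
        assert E == pytest.approx([20.0], abs=1e-9)

    def test_disjoint_reads_pool_rates(self):
        t = make_table(
            [("r1", "gA", 90, 100), ("r2", "gB", 80, 100)]
        )
        p0, E = null_p0(t)
        assert p0 == pytest.approx(0.15, abs=1e-9)
        assert E == pytest.approx([100.0, 100.0], abs=1e-9)

    def test_matches_common_p_em_fixed_point(self, rng):
        from conftest import random_instance
        from tadip import fit_em

        t = random_instance(rng, n=20, k=2)
        p0, _ = null_p0(t)
        fit = fit_em(t, mode="common_p")
        assert p0 == pytest.approx(fit.params.p[0], abs=1e-12)


class TestBetaWeights:
    def test_uniform_beta_gives_unit_weights(self):
        w = beta_weights(np.array([0.1, 0.5, 0.9]), UNIFORM)
        assert w == pytest.approx([1.0, 1.0, 1.0], abs=1e-12)

    def test_density_maximal_at_mode(self):
        cfg = WeightConfig()
        mode = (cfg.a1 - 1) / (cfg.a1 + cfg.a2 - 2)
        grid = np.linspace(0.01, 0.99, 197)
        w = beta_weights(grid, cfg)
        assert beta_weights(np.array([mode]), cfg)[0] >= w.max()

    def test_matches_gamma_function_evaluation(self, rng):
        """Independent density evaluation via log-gamma identities."""
        cfg = WeightConfig(a1=3.5, a2=7.25)
        p = rng.uniform(0.05, 0.95, 20)
        log_norm = (
            math.lgamma(cfg.a1 + cfg.a2)
            - math.lgamma(cfg.a1)
            - math.lgamma(cfg.a2)
        )
        expected = np.exp(
            log_norm
            + (cfg.a1 - 1) * np.log(p)
            + (cfg.a2 - 1) * np.log(1 - p)
        )
        assert beta_weights(p, cfg) == pytest.approx(expected, abs=1e-10)

    def test_boundary_estimates_are_clipped(self):
        w = beta_weights(np.array([0.0, 1.0]), WeightConfig(a1=2, a2=2))
        assert np.all(np.isfinite(w)) and np.all(w >= 0)


class TestDesignMatrix:
    def test_k2_is_all_ones(self):
        assert design_matrix_V(2) == pytest.approx(np.ones((2, 2)))

    def test_k3_off_diagonal_half(self):
        V = design_matrix_V(3)
        assert np.all(np.diag(V) == 1.0)
        off = V[~np.eye(3, dtype=bool)]
        assert off == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 3, 5, 10])
    def test_row_sums_are_two(self, k):
        assert design_matrix_V(k).sum(axis=1) == pytest.approx(np.full(k, 2.0))

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            design_matrix_V(1)


class TestBurden:
    E2 = np.array([1e4, 1e4])

    def test_null_point_gives_zero_statistic(self):
        r = burden_test(np.array([0.1, 0.1]), 0.1, self.E2)
        assert r.statistic == pytest.approx(0.0, abs=1e-20)
        assert r.p_value == pytest.approx(1.0)

    def test_blind_to_opposite_deviations(self):
        # equal weights and equal E: symmetric deviations cancel in the score
        r = burden_test(np.array([0.12, 0.08]), 0.1, self.E2, UNIFORM)
        assert r.statistic == pytest.approx(0.0, abs=1e-15)

    def test_detects_shared_direction(self):
        r = burden_test(np.array([0.13, 0.13]), 0.1, self.E2, UNIFORM)
        assert r.p_value < 1e-6

    def test_zero_effective_count_is_an_error(self):
        with pytest.raises(ValueError, match="effective base count"):
            burden_test(np.array([0.1, 0.2]), 0.1, np.array([100.0, 0.0]))

    def test_statistic_matches_hand_computation(self):
        # uniform weights: C = (2, 2); score = 2(d1 + d2)
        p_hat = np.array([0.12, 0.11])
        p0, E = 0.1, np.array([1000.0, 2000.0])
        r = burden_test(p_hat, p0, E, UNIFORM)
        score = 2 * (0.02 + 0.01)
        var = 4 * p0 * 0.9 / 1000 + 4 * p0 * 0.9 / 2000
        assert r.statistic == pytest.approx(score**2 / var, rel=1e-12)
        assert r.p_value == pytest.approx(stats.chi2.sf(score**2 / var, 1), rel=1e-12)


class TestVCT:
    E2 = np.array([1e4, 1e4])

    def test_null_point_gives_unit_pvalue(self):
        r = vct_test(np.array([0.1, 0.1]), 0.1, self.E2)
        assert r.statistic == pytest.approx(0.0, abs=1e-20)
        assert r.p_value == pytest.approx(1.0)

    def test_detects_opposite_deviations_burden_misses(self):
        p_hat = np.array([0.12, 0.08])
        b = burden_test(p_hat, 0.1, self.E2, UNIFORM)
        v = vct_test(p_hat, 0.1, self.E2, UNIFORM)
        assert b.statistic == pytest.approx(0.0, abs=1e-15)
        assert v.statistic > 0
        assert v.p_value < 0.01

    def test_invariant_to_genome_reordering(self):
        p_hat = np.array([0.012, 0.009, 0.015])
        E = np.array([1e4, 2e4, 5e3])
        r1 = vct_test(p_hat, 0.01, E)
        perm = [2, 0, 1]
        r2 = vct_test(p_hat[perm], 0.01, E[perm])
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)


class TestQuadformPvalue:
    def test_reduces_to_chi2_1(self):
        q = stats.chi2.ppf(0.95, 1)
        assert quadform_pvalue(q, [1.0]) == pytest.approx(0.05, abs=1e-6)

    def test_reduces_to_chi2_2(self):
        q = stats.chi2.ppf(0.95, 2)
        assert quadform_pvalue(q, [1.0, 1.0]) == pytest.approx(0.05, abs=1e-6)

    def test_scaled_equal_eigenvalues(self):
        q = 2.5 * stats.chi2.ppf(0.9, 3)
        assert quadform_pvalue(q, [2.5, 2.5, 2.5]) == pytest.approx(0.1, abs=1e-6)

    def test_general_mixture_matches_monte_carlo(self):
        lam = np.array([2.0, 1.0, 0.5])
        p = quadform_pvalue(4.0, lam)
        rng = np.random.default_rng(1)
        draws = rng.chisquare(1, size=(10**6, 3)) @ lam
        mc = float((draws > 4.0).mean())
        se = math.sqrt(mc * (1 - mc) / 10**6)
        assert abs(p - mc) <= 3 * se

    def test_wildly_unequal_eigenvalues(self):
        # tiny component is negligible; compare with the dominant chi2
        p = quadform_pvalue(5.0, [1.0, 1e-16])
        assert p == pytest.approx(stats.chi2.sf(5.0, 1), abs=1e-6)

    def test_zero_eigenvalues_with_positive_statistic_warns(self):
        with pytest.warns(UserWarning):
            assert quadform_pvalue(1.0, [0.0, 0.0]) == 0.0

    def test_liu_fallback_close_to_imhof(self):
        # moment matching is approximate; body accuracy ~1e-2, tails better
        lam = np.array([2.0, 1.0, 0.5])
        assert _liu_pvalue(4.0 / 2.0, lam / 2.0) == pytest.approx(
            quadform_pvalue(4.0, lam), abs=2e-2
        )
        q_tail = 30.0
        assert _liu_pvalue(q_tail / 2.0, lam / 2.0) == pytest.approx(
            quadform_pvalue(q_tail, lam), rel=0.25
        )


class TestWald:
    def test_null_point(self):
        with pytest.warns(UserWarning, match="poor power"):
            r = wald_test(np.array([0.1, 0.1]), 0.1, np.eye(2))
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_identity_covariance_hand_computation(self):
        with pytest.warns(UserWarning, match="poor power"):
            r = wald_test(np.array([0.2, 0.1]), 0.1, np.eye(2))
        assert r.statistic == pytest.approx(0.01, rel=1e-12)
        assert r.p_value == pytest.approx(stats.chi2.sf(0.01, 1), rel=1e-12)

    def test_diagonal_covariance_matches_explicit_sum(self):
        p_hat = np.array([0.12, 0.09, 0.11])
        sig2 = np.array([1e-4, 2e-4, 5e-5])
        with pytest.warns(UserWarning):
            r = wald_test(p_hat, 0.1, np.diag(sig2))
        expected = float(np.sum((p_hat - 0.1) ** 2 / sig2))
        assert r.statistic == pytest.approx(expected, rel=1e-12)

    def test_singular_covariance_advises_alternatives(self):
        Sigma = np.ones((2, 2))
        with pytest.raises(ValueError, match="burden or variance component"):
            wald_test(np.array([0.2, 0.1]), 0.1, Sigma)


def _mix2_upper_tail(q, lam_hi, lam_lo, n_nodes=4000):
    """Independent tail probability for a 2-term chi-square mixture via
    numerical conditioning on the smaller component."""
    u = (np.arange(n_nodes) + 0.5) / n_nodes
    x = stats.chi2.ppf(u, 1)
    arg = (q[:, None] - lam_lo[:, None] * x[None, :]) / lam_hi[:, None]
    return stats.chi2.sf(np.maximum(arg, 0.0), 1).mean(axis=1)


CAL_REPS = 10000
CAL_P0 = 0.01
CAL_E = np.full(2, 250000.0)


@pytest.fixture(scope="module")
def parametric_phat():
    rng = np.random.default_rng(20240918)
    return rng.binomial(CAL_E.astype(int), CAL_P0, size=(CAL_REPS, 2)) / CAL_E


class TestNullCalibration:
    """Parametric-null size of both tests at the study scale.

    p̂ for each genome is an independent binomial rate at the shared
    mismatch probability; the tests should reject at close to the nominal
    level.  10000 replicates give a binomial SE of ~0.002 on the size.
    """

    P0 = CAL_P0
    E = CAL_E

    def _collapse(self, phat):
        lw = stats.beta.logpdf(np.clip(phat, 1e-6, 1 - 1e-6), 96, 100)
        lw -= lw.max(axis=1, keepdims=True)
        return 2.0 * np.exp(lw)

    def test_burden_size_near_nominal(self, parametric_phat):
        C = self._collapse(parametric_phat)
        d = parametric_phat - self.P0
        sig2 = self.P0 * (1 - self.P0) / self.E
        Q = (C * d).sum(1) ** 2 / (C**2 * sig2).sum(1)
        size = float((Q > stats.chi2.ppf(0.95, 1)).mean())
        assert 0.03 <= size <= 0.07

    def test_vct_size_near_nominal(self, parametric_phat):
        C = self._collapse(parametric_phat)
        d = parametric_phat - self.P0
        sig2 = self.P0 * (1 - self.P0) / self.E
        Q = (C**2 * d**2).sum(1)
        lam = C**2 * sig2
        pv = _mix2_upper_tail(Q, lam.max(1), lam.min(1))
        size = float((pv < 0.05).mean())
        assert 0.03 <= size <= 0.07

    def test_vectorized_stats_agree_with_test_functions(self, parametric_phat):
        """The vectorized calibration path reproduces burden_test/vct_test."""
        sub = parametric_phat[:25]
        C = self._collapse(sub)
        d = sub - self.P0
        sig2 = self.P0 * (1 - self.P0) / self.E
        Qb = (C * d).sum(1) ** 2 / (C**2 * sig2).sum(1)
        Qv = (C**2 * d**2).sum(1)
        lam = C**2 * sig2
        pv = _mix2_upper_tail(Qv, lam.max(1), lam.min(1))
        for i in range(len(sub)):
            b = burden_test(sub[i], self.P0, self.E)
            v = vct_test(sub[i], self.P0, self.E)
            assert b.statistic == pytest.approx(Qb[i], rel=1e-9)
            assert v.p_value == pytest.approx(pv[i], abs=2e-3)

    def test_power_under_separated_alternative(self):
        """Both tests essentially always reject when two genomes differ
        clearly (rates 0.005 vs 0.015 at ~1e5 effective bases)."""
        rng = np.random.default_rng(99)
        E = np.full(2, 1e5)
        reps = 200
        phat = rng.binomial(E.astype(int), [0.005, 0.015], size=(reps, 2)) / E
        p0 = (E * phat).sum(1) / E.sum()
        hits_b = hits_v = 0
        for i in range(reps):
            b = burden_test(phat[i], p0[i], E)
            v = vct_test(phat[i], p0[i], E)
            hits_b += b.p_value < 0.05
            hits_v += v.p_value < 0.05
        assert hits_b / reps >= 0.95
        assert hits_v / reps >= 0.95
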