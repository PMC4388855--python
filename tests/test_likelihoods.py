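"""Likelihood evaluation: full, conditional, marginal, profile variants."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import hypergeom

from twobytwo import (
    ParamPoint,
    PoissonTable,
    Table2x2,
    conditional_mle,
    enumerate_sample_space,
    estimated_loglik,
    likelihood_curve,
    log_normalizer,
    loglik_conditional,
    loglik_full,
    loglik_marginal,
    modified_profile_loglik,
    poisson_conditional_logpmf,
    profile_loglik,
    psi_hat_unconditional,
)
from twobytwo.likelihoods import loglik_full_canonical

from conftest import random_interior_table


def log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


class TestFullLikelihood:
    def test_direct_binomial_arithmetic(self, worked_example):
        pt = ParamPoint.from_probs(0.5, 0.5, 10, 10)
        expected = log_binom(10, 1) + log_binom(10, 5) + 20 * math.log(0.5)
        assert loglik_full(worked_example, pt) == pytest.approx(expected, abs=1e-12)

    def test_boundary_point_probability_one(self):
        t = Table2x2(10, 10, 10, 10)
        pt = ParamPoint.from_probs(1.0, 1.0, 10, 10)
        assert loglik_full(t, pt) == 0.0

    def test_boundary_point_incompatible_counts(self, worked_example):
        pt = ParamPoint.from_probs(1.0, 1.0, 10, 10)
        assert loglik_full(worked_example, pt) == -math.inf

    def test_canonical_form_agrees_with_probs_form(self, rng):
        for _ in range(20):
            t = random_interior_table(rng)
            pt = ParamPoint.from_probs(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95), t.n1, t.n2)
            assert loglik_full_canonical(t, pt.psi, pt.lambda_can) == pytest.approx(
                loglik_full(t, pt), abs=1e-12
            )

    def test_normalizes_over_unconditioned_grid(self):
        pt = ParamPoint.from_probs(0.23, 0.71, 10, 10)
        total = sum(
            math.exp(loglik_full(Table2x2(y1, 10, y2, 10), pt))
            for y1, y2, _ in enumerate_sample_space(10, 10)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLogNormalizer:
    def test_vandermonde_identity_at_null(self):
        # sum_u C(10,u) C(10,6-u) = C(20,6) = 38760
        assert log_normalizer(0.0, 6, 10, 10) == pytest.approx(math.log(38760), abs=1e-10)

    def test_degenerate_support_single_term(self):
        assert log_normalizer(0.0, 0, 10, 10) == 0.0

    @pytest.mark.parametrize("psi", [300.0, 500.0, -300.0, -500.0])
    def test_extreme_psi_dominant_term(self, psi):
        """Far in the tails the extreme support point dominates, no overflow."""
        val = log_normalizer(psi, 6, 10, 10)
        u = 6 if psi > 0 else 0
        dominant = float(log_binom(10, u) + log_binom(10, 6 - u)) + psi * u
        assert val == pytest.approx(dominant, abs=1e-6)


class TestConditionalLikelihood:
    def test_null_equals_hypergeometric(self, worked_example):
        expected = math.log(2520 / 38760)  # C(10,1) C(10,5) / C(20,6)
        assert loglik_conditional(worked_example, 0.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(hypergeom.logpmf(1, 20, 10, 6), abs=1e-10)

    def test_degenerate_support_is_certain(self):
        assert loglik_conditional(Table2x2(0, 10, 0, 10), 1.7) == 0.0

    @pytest.mark.parametrize("psi", [-3.0, 0.0, 1.5, 4.0])
    def test_normalizes_over_conditioned_support(self, worked_example, psi):
        t = worked_example
        total = sum(
            math.exp(loglik_conditional(Table2x2(y1, 10, 6 - y1, 10), psi))
            for y1 in t.conditioned_support()
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_likelihood_ratio(self, worked_example):
        lr = math.exp(
            loglik_conditional(worked_example, -2.08) - loglik_conditional(worked_example, 0.0)
        )
        assert lr == pytest.approx(6.89, abs=0.01)


class TestMarginalLikelihood:
    def test_factorization_identity(self, rng):
        """Full = conditional + marginal in log space, exactly."""
        for _ in range(25):
            t = random_interior_table(rng)
            pt = ParamPoint.from_probs(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95), t.n1, t.n2)
            lhs = loglik_full_canonical(t, pt.psi, pt.lambda_can)
            rhs = loglik_conditional(t, pt.psi) + loglik_marginal(t.y_plus, t.n1, t.n2, pt)
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_normalizes_over_y_plus(self):
        pt = ParamPoint.from_probs(0.3, 0.6, 7, 13)
        total = sum(math.exp(loglik_marginal(y, 7, 13, pt)) for y in range(21))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("psi", [0.5, 1.5, 3.0])
    def test_equal_n_symmetry_in_psi(self, psi):
        """Balanced designs: the marginal likelihood of y+ is even in psi
        at fixed marginal success probability."""
        for y_plus in (4, 6, 10):
            a = loglik_marginal(y_plus, 10, 10, ParamPoint.from_orthogonal(psi, 0.4, 10, 10))
            b = loglik_marginal(y_plus, 10, 10, ParamPoint.from_orthogonal(-psi, 0.4, 10, 10))
            assert a == pytest.approx(b, abs=1e-10)

    def test_null_reduces_to_binomial(self):
        from scipy.stats import binom

        pt = ParamPoint.from_probs(0.35, 0.35, 10, 10)
        for y in range(21):
            assert loglik_marginal(y, 10, 10, pt) == pytest.approx(
                float(binom.logpmf(y, 20, 0.35)), abs=1e-10
            )


class TestConditionalMLE:
    def test_worked_example(self, worked_example):
        assert conditional_mle(worked_example) == pytest.approx(-2.08, abs=0.005)

    def test_symmetric_table(self, symmetric_table):
        assert conditional_mle(symmetric_table) == pytest.approx(0.0, abs=1e-9)

    def test_boundary_support(self):
        assert conditional_mle(Table2x2(0, 10, 5, 10)) == -math.inf
        assert conditional_mle(Table2x2(10, 10, 1, 10)) == math.inf

    def test_agrees_with_grid_refinement_oracle(self, worked_example):
        """Optimizer-free oracle: the MLE solves E_psi[Y1 | y+] = y1, with
        the tilted mean computed by direct summation and the root located
        by iterated grid refinement over psi in [-30, 30]."""
        from scipy.special import comb

        t = worked_example
        u = np.arange(max(0, t.y_plus - t.n2), min(t.n1, t.y_plus) + 1)
        w0 = comb(t.n1, u) * comb(t.n2, t.y_plus - u)

        def mean_minus_y1(psi):
            w = w0 * np.exp(psi * (u - u.mean()))  # centered for stability
            return (w @ u) / w.sum() - t.y1

        lo, hi = -30.0, 30.0
        for _ in range(4):
            grid = np.linspace(lo, hi, 2001)
            sign = np.sign([mean_minus_y1(p) for p in grid])
            i = int(np.argmax(sign > 0))  # first grid point past the root
            lo, hi = grid[i - 1], grid[i]
        oracle = (lo + hi) / 2
        assert conditional_mle(t) == pytest.approx(oracle, abs=1e-8)

    def test_shrinks_toward_null_on_full_grid(self):
        """Conditioning pulls the MLE weakly toward 0 for every table."""
        for y1, y2, psi_u in enumerate_sample_space(10, 10):
            psi_c = conditional_mle(Table2x2(y1, 10, y2, 10))
            if math.isfinite(psi_u) and math.isfinite(psi_c):
                lo, hi = sorted((0.0, psi_u))
                assert lo - 1e-9 <= psi_c <= hi + 1e-9


class TestProfileVariants:
    def test_profile_at_unconditional_mle_is_global_max(self, worked_example):
        t = worked_example
        psi_hat = psi_hat_unconditional(t)
        pt_hat = ParamPoint.from_probs(t.y1 / t.n1, t.y2 / t.n2, t.n1, t.n2)
        global_max = loglik_full(t, pt_hat)
        assert profile_loglik(t, psi_hat) == pytest.approx(global_max, abs=1e-10)

    def test_profile_equals_estimated_standardized(self, worked_example):
        """Orthogonality of lambda*: profiling and plugging in give the
        same standardized curve."""
        t = worked_example
        grid = np.linspace(-6, 2, 161)
        prof = np.array([profile_loglik(t, p) for p in grid])
        est = np.array([estimated_loglik(t, p) for p in grid])
        sp = np.exp(prof - prof.max())
        se = np.exp(est - est.max())
        assert np.abs(sp - se).max() < 1e-6

    def test_profile_dominates_estimated_pointwise(self, rng):
        for _ in range(10):
            t = random_interior_table(rng)
            for psi in (-3.0, -0.7, 0.0, 1.2, 4.0):
                assert profile_loglik(t, psi) >= estimated_loglik(t, psi) - 1e-10

    def test_modified_profile_tracks_conditional(self, worked_example):
        t = worked_example
        grid = np.linspace(-6, 2, 321)
        c = np.array([loglik_conditional(t, p) for p in grid])
        m = np.array([modified_profile_loglik(t, p) for p in grid])
        sc = np.exp(c - c.max())
        sm = np.exp(m - m.max())
        assert np.abs(sc - sm).max() < 0.01

    def test_modified_profile_symmetric_table_max_at_zero(self, symmetric_table):
        grid = np.linspace(-2, 2, 401)
        m = [modified_profile_loglik(symmetric_table, p) for p in grid]
        assert grid[int(np.argmax(m))] == pytest.approx(0.0, abs=0.02)

    def test_curvature_adjustment_swap_invariance(self):
        """Equal group sizes: the nuisance information is unchanged when
        the two fitted success probabilities are exchanged."""
        j = lambda p1, p2, n: n * p1 * (1 - p1) + n * p2 * (1 - p2)
        assert j(0.2, 0.7, 10) == pytest.approx(j(0.7, 0.2, 10), abs=1e-15)

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError):
            modified_profile_loglik(Table2x2(0, 10, 0, 10), 1.0)


class TestPoissonReduction:
    def test_equal_means_equal_probs(self):
        pt = PoissonTable(1, 9, 5, 5, 2.0, 2.0, 2.0, 2.0)
        t = Table2x2(1, 10, 5, 10)
        assert poisson_conditional_logpmf(pt) == pytest.approx(
            loglik_full(t, ParamPoint.from_probs(0.5, 0.5, 10, 10)), abs=1e-12
        )

    def test_randomized_substitution(self, rng):
        """Conditioning Poisson cells on row totals recovers the dual
        binomial pmf under the mean-ratio substitution."""
        for _ in range(20):
            mu = rng.uniform(0.5, 5.0, size=4)
            m11, m12 = int(rng.integers(0, 8)), int(rng.integers(0, 8))
            m21, m22 = int(rng.integers(0, 8)), int(rng.integers(0, 8))
            if m11 + m12 == 0 or m21 + m22 == 0:
                continue
            pt = PoissonTable(m11, m12, m21, m22, *mu)
            t = Table2x2(m11, m11 + m12, m21, m21 + m22)
            pp = ParamPoint.from_probs(
                mu[0] / (mu[0] + mu[1]), mu[2] / (mu[2] + mu[3]), t.n1, t.n2
            )
            assert poisson_conditional_logpmf(pt) == pytest.approx(
                loglik_full(t, pp), abs=1e-12
            )

    def test_normalizes_with_margins_fixed(self):
        mu = (1.3, 0.6, 2.1, 0.9)
        total = sum(
            math.exp(poisson_conditional_logpmf(PoissonTable(a, 5 - a, c, 4 - c, *mu)))
            for a in range(6)
            for c in range(5)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLikelihoodCurve:
    def test_standardized_max_is_one(self, worked_example):
        curve = likelihood_curve(worked_example, "conditional", n_points=101)
        s = curve.standardized
        assert s.max() == pytest.approx(1.0)
        assert np.all(s <= 1.0)
        assert curve.psi_max == pytest.approx(conditional_mle(worked_example), abs=0.05)

    def test_rejects_bad_grid(self):
        from twobytwo import LikelihoodCurve

        with pytest.raises(ValueError):
            LikelihoodCurve("conditional", np.array([0.0, 0.0, 1.0]), np.zeros(3))

    def test_unknown_kind(self, worked_example):
        with pytest.raises(ValueError):
            likelihood_curve(worked_example, "posterior")

    def test_csv_round_trip(self, worked_example, tmp_path):
        import pandas as pd

        curve = likelihood_curve(worked_example, "conditional", n_points=51)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["psi", "loglik", "standardized"]
        np.testing.assert_allclose(df["psi"], curve.psi)
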