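"""Beta-belief algebra against independent numerical oracles.

Every closed form here is checked against direct quadrature of the
densities on a fine grid, and the KL-optimal compression against a
brute-force minimization of the numerically integrated divergence.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import betaln

from repgame.beta_math import (
    BeliefState,
    MixtureBelief,
    beta_from_moments,
    beta_log_moments,
    beta_mean,
    beta_variance,
    cap_evidence,
    compress_kl_optimal,
    compress_moment_matching,
    compress_weighted,
    kl_beta,
    mixture_moments,
    solve_log_moments,
    weighted_mixture_log_moments,
    weighted_mixture_moments,
)

# midpoint grid on (0, 1): handles the integrable endpoint singularities
# of exponents in (-1, 0)
_N = 20000
_X = (np.arange(_N) + 0.5) / _N


def _density(b: BeliefState) -> np.ndarray:
    return np.exp(
        b.mu * np.log(_X) + b.lam * np.log1p(-_X) - betaln(b.mu + 1.0, b.lam + 1.0)
    )


def _quad_mean(b: BeliefState) -> float:
    return float(np.mean(_X * _density(b)))


def _quad_kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.mean(p * (np.log(p) - np.log(q))))


exponents = st.floats(min_value=-0.9, max_value=30.0)
states = st.builds(BeliefState, exponents, exponents)

# quadrature oracles need integrands without endpoint singularities, so
# their comparisons run on the count domain; negative-exponent behavior
# is pinned by exact closed-form cases instead
smooth_states = st.builds(
    BeliefState, st.floats(0.0, 30.0), st.floats(0.0, 30.0)
)


class TestMoments:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (BeliefState(0, 0), 0.5),
            (BeliefState(3, 1), 2.0 / 3.0),
            (BeliefState(7.5, 7.5), 0.5),
        ],
    )
    def test_mean_closed_form(self, state, expected):
        assert beta_mean(state) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "state, expected",
        [
            (BeliefState(0, 0), 1.0 / 12.0),
            (BeliefState(2, 0), 3.0 / 80.0),
        ],
    )
    def test_variance_closed_form(self, state, expected):
        assert beta_variance(state) == pytest.approx(expected, abs=1e-12)

    @given(smooth_states)
    @settings(max_examples=50, deadline=None)
    def test_mean_and_variance_match_quadrature(self, b):
        dens = _density(b)
        m = float(np.mean(_X * dens))
        v = float(np.mean((_X - m) ** 2 * dens))
        assert beta_mean(b) == pytest.approx(m, rel=1e-3, abs=1e-5)
        assert beta_variance(b) == pytest.approx(v, rel=1e-3, abs=1e-5)

    @given(states)
    @settings(max_examples=50, deadline=None)
    def test_variance_below_bernoulli_bound(self, b):
        m = beta_mean(b)
        assert 0.0 < beta_variance(b) < m * (1.0 - m)

    @pytest.mark.parametrize(
        "state, expected",
        [
            (BeliefState(0, 0), (-1.0, -1.0)),
            (BeliefState(1, 0), (-0.5, -1.5)),
        ],
    )
    def test_log_moments_closed_form(self, state, expected):
        got = beta_log_moments(state)
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)

    @given(states)
    @settings(max_examples=50, deadline=None)
    def test_log_moments_negative_and_symmetric(self, b):
        lx, l1x = beta_log_moments(b)
        assert lx < 0.0 and l1x < 0.0
        mx, m1x = beta_log_moments(BeliefState(b.lam, b.mu))
        assert mx == pytest.approx(l1x, abs=1e-12)


class TestKL:
    def test_zero_at_equality(self):
        b = BeliefState(4.2, 1.3)
        assert kl_beta(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature(self):
        p = BeliefState(2, 0)
        q = BeliefState(0, 0)
        assert kl_beta(p, q) == pytest.approx(
            _quad_kl(_density(p), _density(q)), rel=1e-3
        )

    def test_asymmetric(self):
        p, q = BeliefState(5, 1), BeliefState(2, 0)
        assert kl_beta(p, q) != pytest.approx(kl_beta(q, p), rel=1e-3)

    @given(states, states)
    @settings(max_examples=100, deadline=None)
    def test_nonnegative(self, p, q):
        assert kl_beta(p, q) >= -1e-12

    def test_random_pairs_match_quadrature(self, rng):
        for _ in range(20):
            p = BeliefState(*rng.uniform(0, 10, 2))
            q = BeliefState(*rng.uniform(0, 10, 2))
            assert kl_beta(p, q) == pytest.approx(
                _quad_kl(_density(p), _density(q)), rel=1e-3, abs=1e-5
            )


class TestMixtureMoments:
    def test_degenerate_weight_one(self):
        m = MixtureBelief(1.0, BeliefState(3, 1), BeliefState(0, 9))
        mean, var = mixture_moments(m)
        assert mean == pytest.approx(beta_mean(m.comp_h), abs=1e-14)
        assert var == pytest.approx(beta_variance(m.comp_h), abs=1e-14)

    def test_worked_symmetric_example(self):
        m = MixtureBelief(0.5, BeliefState(2, 0), BeliefState(0, 2))
        mean, var = mixture_moments(m)
        assert mean == pytest.approx(0.5, abs=1e-12)
        assert var == pytest.approx(0.1, abs=1e-12)

    @given(st.floats(0.05, 0.95), states, states)
    @settings(max_examples=100, deadline=None)
    def test_law_of_total_variance(self, w, a, b):
        _, var = weighted_mixture_moments((w, 1 - w), (a, b))
        within = w * beta_variance(a) + (1 - w) * beta_variance(b)
        assert var >= within - 1e-12


class TestMomentMatchingCompression:
    def test_round_trip_identity(self):
        m = MixtureBelief(1.0, BeliefState(3, 1), BeliefState(0, 0))
        assert compress_moment_matching(m) == BeliefState(3, 1)

    def test_worked_example_negative_exponents(self):
        m = MixtureBelief(0.5, BeliefState(2, 0), BeliefState(0, 2))
        out = compress_moment_matching(m)
        assert out.mu == pytest.approx(-0.25, abs=1e-12)
        assert out.lam == pytest.approx(-0.25, abs=1e-12)

    @given(st.floats(0.05, 0.95), states, states)
    @settings(max_examples=150, deadline=None)
    def test_conserves_mean_and_variance(self, w, a, b):
        m = MixtureBelief(w, a, b)
        out = compress_moment_matching(m)
        mean, var = mixture_moments(m)
        assert beta_mean(out) == pytest.approx(mean, rel=1e-10)
        assert beta_variance(out) == pytest.approx(var, rel=1e-10)

    def test_rejects_impossible_moments(self):
        with pytest.raises(ValueError):
            beta_from_moments(0.5, 0.25)  # bound mean(1-mean) exactly
        with pytest.raises(ValueError):
            beta_from_moments(0.5, 0.0)


class TestKLOptimalCompression:
    def test_round_trip_identity(self):
        m = MixtureBelief(1.0, BeliefState(5, 2), BeliefState(0, 0))
        assert compress_kl_optimal(m) == BeliefState(5, 2)

    def test_symmetric_mixture_gives_symmetric_state(self):
        m = MixtureBelief(0.5, BeliefState(2, 0), BeliefState(0, 2))
        out = compress_kl_optimal(m)
        assert out.mu == pytest.approx(out.lam, abs=1e-9)

    def test_conserves_log_moments_on_random_mixtures(self, rng):
        # the defining contract, on at least 100 random mixtures
        for _ in range(120):
            w = rng.uniform(0.05, 0.95)
            a = BeliefState(*rng.uniform(0, 20, 2))
            b = BeliefState(*rng.uniform(0, 20, 2))
            out = compress_kl_optimal(MixtureBelief(w, a, b))
            lx, l1x = weighted_mixture_log_moments((w, 1 - w), (a, b))
            got = beta_log_moments(out)
            assert abs(got[0] - lx) < 1e-8
            assert abs(got[1] - l1x) < 1e-8

    def test_agrees_with_brute_force_minimization(self, rng):
        """Independent oracle: minimize the quadrature KL between the
        mixture density and a candidate beta over (mu, lam) directly."""
        for _ in range(12):
            w = rng.uniform(0.05, 0.95)
            a = BeliefState(*rng.uniform(0, 20, 2))
            b = BeliefState(*rng.uniform(0, 20, 2))
            mix = w * _density(a) + (1 - w) * _density(b)

            def quad_kl(params):
                q = np.exp(
                    params[0] * np.log(_X)
                    + params[1] * np.log1p(-_X)
                    - betaln(params[0] + 1.0, params[1] + 1.0)
                )
                return _quad_kl(mix, q)

            ours = compress_kl_optimal(MixtureBelief(w, a, b))
            start = compress_moment_matching(MixtureBelief(w, a, b))
            res = minimize(
                quad_kl,
                [start.mu * 1.05 + 0.1, start.lam * 0.95],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
            )
            # our solution must be at least as good as the oracle's optimum
            assert quad_kl([ours.mu, ours.lam]) <= res.fun + 1e-6
            assert ours.mu == pytest.approx(res.x[0], abs=2e-2)
            assert ours.lam == pytest.approx(res.x[1], abs=2e-2)

    def test_methods_differ_on_asymmetric_mixture(self):
        m = MixtureBelief(0.3, BeliefState(9, 1), BeliefState(1, 4))
        kl = compress_kl_optimal(m)
        mm = compress_moment_matching(m)
        assert abs(kl.mu - mm.mu) > 1e-3 or abs(kl.lam - mm.lam) > 1e-3

    def test_solver_reports_nonconvergence(self):
        with pytest.raises(RuntimeError):
            solve_log_moments(-0.5, -0.5, BeliefState(0, 0), max_iter=0)


class TestCapEvidence:
    def test_within_capacity_unchanged(self):
        b = BeliefState(10, 5)
        assert cap_evidence(b, 300.0) is b

    @given(states, st.floats(5.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_preserves_mean(self, b, cap):
        out = cap_evidence(b, cap)
        assert beta_mean(out) == pytest.approx(beta_mean(b), rel=1e-12)
        assert out.mu + out.lam + 2.0 <= cap + 1e-9


def test_compress_weighted_multi_component(rng):
    """N-component mixtures (audience merging) obey the same contracts."""
    ws = rng.dirichlet(np.ones(5))
    comps = [BeliefState(*rng.uniform(0, 15, 2)) for _ in range(5)]
    mm = compress_weighted(ws, comps, method="moment_matching")
    mean, var = weighted_mixture_moments(ws, comps)
    assert beta_mean(mm) == pytest.approx(mean, rel=1e-10)
    assert beta_variance(mm) == pytest.approx(var, rel=1e-10)
    kl = compress_weighted(ws, comps, method="kl_optimal")
    lx, l1x = weighted_mixture_log_moments(ws, comps)
    got = beta_log_moments(kl)
    assert abs(got[0] - lx) < 1e-8 and abs(got[1] - l1x) < 1e-8


def test_compress_weighted_identical_components_exact():
    b = BeliefState(2.5, 0.5)
    for method in ("kl_optimal", "moment_matching"):
        assert compress_weighted((0.3, 0.7), (b, b), method=method) == b
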