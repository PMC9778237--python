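"""Algebra on beta-form belief states.

An agent's knowledge about one honesty value ``x`` is a beta distribution

    P(x | I) = x**mu * (1-x)**lam / B(mu+1, lam+1),      I = (mu, lam),

where ``mu`` and ``lam`` act as pseudo-counts of honest and dishonest
statements.  The exponents may take any value in (-1, inf); negative
exponents arise legitimately when a mixture of betas is compressed back
into a single beta, so they are not clamped.

Knowledge updates produce *mixtures* of beta distributions, which bounded
rationality forces back into a single beta.  Two compression rules are
implemented:

``compress_kl_optimal``
    minimizes D_KL(mixture || beta), which conserves the moments
    <ln x> and <ln(1-x)> (solved by damped Newton on the digamma system);

``compress_moment_matching``
    conserves the mean and variance (closed form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

from scipy.special import digamma, zeta


class BeliefState(NamedTuple):
    """Parameters (mu, lam) of a beta-form belief; both must exceed -1."""

    mu: float
    lam: float

    def is_valid(self) -> bool:
        return self.mu > -1.0 and self.lam > -1.0

    def shifted(self, d_mu: float = 0.0, d_lam: float = 0.0) -> "BeliefState":
        return BeliefState(self.mu + d_mu, self.lam + d_lam)


#: the zero-count (uniform) prior
UNIFORM = BeliefState(0.0, 0.0)


def _ln_beta_fn(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def beta_mean(b: BeliefState) -> float:
    """Expected honesty (mu+1)/(mu+lam+2)."""
    mu, lam = b
    return (mu + 1.0) / (mu + lam + 2.0)


def beta_variance(b: BeliefState) -> float:
    """Variance mean*(1-mean)/(mu+lam+3)."""
    mu, lam = b
    m = (mu + 1.0) / (mu + lam + 2.0)
    return m * (1.0 - m) / (mu + lam + 3.0)


def beta_log_moments(b: BeliefState) -> Tuple[float, float]:
    """(<ln x>, <ln(1-x)>) via digamma; both are strictly negative."""
    mu, lam = b
    t = float(digamma(mu + lam + 2.0))
    return float(digamma(mu + 1.0)) - t, float(digamma(lam + 1.0)) - t


def kl_beta(p: BeliefState, q: BeliefState) -> float:
    """Kullback-Leibler divergence D_KL(Beta(p) || Beta(q)), closed form."""
    lx, l1x = beta_log_moments(p)
    return (
        _ln_beta_fn(q.mu + 1.0, q.lam + 1.0)
        - _ln_beta_fn(p.mu + 1.0, p.lam + 1.0)
        + (p.mu - q.mu) * lx
        + (p.lam - q.lam) * l1x
    )


@dataclass(frozen=True)
class MixtureBelief:
    """Two-component beta mixture produced by a credibility-weighted update.

    ``weight_h`` is the credibility y_J assigned to the honest branch,
    ``comp_h``/``comp_nh`` the belief states conditional on the message
    having been honest / dishonest.
    """

    weight_h: float
    comp_h: BeliefState
    comp_nh: BeliefState

    def as_weighted(self) -> Tuple[Tuple[float, float], Tuple[BeliefState, BeliefState]]:
        return (self.weight_h, 1.0 - self.weight_h), (self.comp_h, self.comp_nh)


def weighted_mixture_moments(
    weights: Sequence[float], comps: Sequence[BeliefState]
) -> Tuple[float, float]:
    """Mean and variance of a weighted beta mixture.

    Uses the shifted form of the second-moment identity,
    var = sum_i w_i (var_i + (mean_i - mean)**2), which is immune to the
    catastrophic cancellation that E[x^2] - mean^2 suffers for very
    sharp components.
    """
    ms = [beta_mean(c) for c in comps]
    mean = sum(w * m for w, m in zip(weights, ms))
    var = sum(
        w * (beta_variance(c) + (m - mean) ** 2)
        for w, m, c in zip(weights, ms, comps)
    )
    return mean, var


def weighted_mixture_log_moments(
    weights: Sequence[float], comps: Sequence[BeliefState]
) -> Tuple[float, float]:
    """(<ln x>, <ln(1-x)>) of a mixture: the weighted sum of component moments."""
    lx = 0.0
    l1x = 0.0
    for w, c in zip(weights, comps):
        a, b = beta_log_moments(c)
        lx += w * a
        l1x += w * b
    return lx, l1x


def mixture_moments(m: MixtureBelief) -> Tuple[float, float]:
    weights, comps = m.as_weighted()
    return weighted_mixture_moments(weights, comps)


def beta_from_moments(mean: float, variance: float) -> BeliefState:
    """Invert (mean, variance) -> (mu, lam); the moment-matching core.

    Raises ``ValueError`` when no beta distribution has these moments,
    i.e. unless 0 < variance < mean*(1-mean).
    """
    bound = mean * (1.0 - mean)
    if not (0.0 < variance < bound):
        raise ValueError(
            f"no beta distribution with mean {mean!r} and variance {variance!r}"
        )
    s = bound / variance - 1.0
    return BeliefState(mean * s - 1.0, (1.0 - mean) * s - 1.0)


def cap_evidence(b: BeliefState, capacity: float) -> BeliefState:
    """Rescale a belief to at most ``capacity`` total pseudo-counts.

    The mean is preserved exactly; only the concentration (mu+lam+2) is
    clipped.  Models a finite evidence memory: without such a bound,
    opinions circulating through the population re-amplify along loops
    and the pseudo-counts grow exponentially, freezing every mean.
    States within capacity are returned unchanged.
    """
    t = b.mu + b.lam + 2.0
    if t <= capacity:
        return b
    m = (b.mu + 1.0) / t
    return BeliefState(m * capacity - 1.0, (1.0 - m) * capacity - 1.0)


def _normalized(weights: Sequence[float], comps: Sequence[BeliefState]):
    """Drop zero-weight components and normalize; collapse identical components."""
    pairs = [(w, BeliefState(*c)) for w, c in zip(weights, comps) if w > 0.0]
    if not pairs:
        raise ValueError("mixture has no positive-weight component")
    total = sum(w for w, _ in pairs)
    ws = [w / total for w, _ in pairs]
    cs = [c for _, c in pairs]
    first = cs[0]
    if all(c == first for c in cs[1:]):
        return None, first  # degenerate: exact answer available
    return (ws, cs), None


def compress_weighted(
    weights: Sequence[float],
    comps: Sequence[BeliefState],
    method: str = "kl_optimal",
) -> BeliefState:
    """Compress a weighted beta mixture into one beta state.

    ``method`` is ``"kl_optimal"`` (conserves <ln x>, <ln(1-x)>) or
    ``"moment_matching"`` (conserves mean and variance).  Degenerate
    mixtures (a single effective component) are returned exactly.
    """
    mix, exact = _normalized(weights, comps)
    if exact is not None:
        return exact
    ws, cs = mix
    mean, var = weighted_mixture_moments(ws, cs)
    try:
        mm = beta_from_moments(mean, var)
    except ValueError:
        # mathematically var is strictly inside (0, mean(1-mean)) for any
        # nondegenerate mixture; reaching this point means floating-point
        # underflow, so the dominant component is the exact answer to
        # machine precision
        return cs[max(range(len(ws)), key=ws.__getitem__)]
    if method == "moment_matching":
        return mm
    if method != "kl_optimal":
        raise ValueError(f"unknown compression method: {method!r}")
    lx, l1x = weighted_mixture_log_moments(ws, cs)
    return solve_log_moments(lx, l1x, init=mm)


def compress_moment_matching(m: MixtureBelief) -> BeliefState:
    weights, comps = m.as_weighted()
    return compress_weighted(weights, comps, method="moment_matching")


def compress_kl_optimal(m: MixtureBelief) -> BeliefState:
    weights, comps = m.as_weighted()
    return compress_weighted(weights, comps, method="kl_optimal")


def solve_log_moments(
    target_lx: float,
    target_l1x: float,
    init: BeliefState,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> BeliefState:
    """Find the beta state whose log-moments equal the targets.

    Solves psi(mu+1) - psi(mu+lam+2) = target_lx and
    psi(lam+1) - psi(mu+lam+2) = target_l1x by damped Newton iteration
    (step halving until the residual norm decreases, respecting the
    domain mu, lam > -1).  ``init`` is typically the moment-matching
    solution, which is already close for tight mixtures.
    """
    mu, lam = init
    # absolute tolerance, scaled up for targets far from O(1) where the
    # digamma evaluations themselves carry rounding of that order
    tol = tol * max(1.0, abs(target_lx), abs(target_l1x))
    t = mu + lam + 2.0
    ps = float(digamma(t))
    f1 = float(digamma(mu + 1.0)) - ps - target_lx
    f2 = float(digamma(lam + 1.0)) - ps - target_l1x
    for _ in range(max_iter):
        if abs(f1) < tol and abs(f2) < tol:
            return BeliefState(mu, lam)
        pt = float(zeta(2.0, mu + lam + 2.0))  # trigamma
        a11 = float(zeta(2.0, mu + 1.0)) - pt
        a22 = float(zeta(2.0, lam + 1.0)) - pt
        det = a11 * a22 - pt * pt
        d_mu = -(f1 * a22 + pt * f2) / det
        d_lam = -(a11 * f2 + pt * f1) / det
        r0 = f1 * f1 + f2 * f2
        step = 1.0
        while True:
            n_mu = mu + step * d_mu
            n_lam = lam + step * d_lam
            if n_mu > -1.0 and n_lam > -1.0:
                t = n_mu + n_lam + 2.0
                ps = float(digamma(t))
                g1 = float(digamma(n_mu + 1.0)) - ps - target_lx
                g2 = float(digamma(n_lam + 1.0)) - ps - target_l1x
                if g1 * g1 + g2 * g2 < r0 or step < 1e-12:
                    break
            else:
                if step < 1e-12:
                    raise RuntimeError(
                        "log-moment inversion left the domain mu, lam > -1"
                    )
            step *= 0.5
        mu, lam, f1, f2 = n_mu, n_lam, g1, g2
    if abs(f1) < tol and abs(f2) < tol:
        return BeliefState(mu, lam)
    raise RuntimeError(
        f"log-moment inversion did not converge: residuals ({f1:.3e}, {f2:.3e})"
    )
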