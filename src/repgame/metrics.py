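"""Ensemble statistics: reputation, informedness, agreement, neighborhoods.

Reputation combines everyone's beta beliefs about an agent by summing
their exponents (the normalized product of the independent beliefs):

    reputation_i = (sum_j mu_ji + 1) / (sum_j mu_ji + sum_j lam_ji + 2),

which equals the beta-function ratio B(S_mu+2, S_lam+1)/B(S_mu+1, S_lam+1)
and automatically down-weights uninformed contributors.  Informedness and
agreement are centered dot products of belief-mean vectors against the
true honesties and against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .agent_state import Population
from .beta_math import BeliefState, beta_mean
from .engine import RealizationResult


def _ln_beta_fn(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def combined_reputation(
    states: Sequence[BeliefState],
    method: str = "closed_form",
    clip_negative: bool = True,
) -> float:
    """Mean honesty under the product of the contributors' beliefs.

    ``method="closed_form"`` evaluates (S_mu+1)/(S_mu+S_lam+2);
    ``method="beta_ratio"`` evaluates the equivalent ratio of beta
    functions through log-gamma (the cross-check form).

    Belief compression can leave individual exponents in (-1, 0), and a
    sum of many such exponents falls below -1, where the product belief
    is no longer normalizable.  With ``clip_negative`` (the default)
    each contributor is clipped into the count domain [0, inf) first:
    only positive evidence counts toward a reputation, and uninformed
    contributors drop out of the sums entirely.
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one contributor")
    if clip_negative:
        s_mu = sum(max(s.mu, 0.0) for s in states)
        s_lam = sum(max(s.lam, 0.0) for s in states)
    else:
        s_mu = sum(s.mu for s in states)
        s_lam = sum(s.lam for s in states)
    if s_mu <= -1.0 or s_lam <= -1.0:
        raise ValueError("summed exponents left the normalizable domain")
    if method == "closed_form":
        return (s_mu + 1.0) / (s_mu + s_lam + 2.0)
    if method == "beta_ratio":
        return math.exp(
            _ln_beta_fn(s_mu + 2.0, s_lam + 1.0) - _ln_beta_fn(s_mu + 1.0, s_lam + 1.0)
        )
    raise ValueError(f"unknown method {method!r}")


def all_reputations(pop: Population) -> np.ndarray:
    """Combined reputation of every agent in the eyes of all others."""
    out = np.empty(pop.n)
    for i in range(pop.n):
        out[i] = combined_reputation(
            [pop.agents[j].beliefs[i] for j in range(pop.n) if j != i]
        )
    return out


def belief_mean_matrix(pop: Population) -> np.ndarray:
    """M[i, k] = mean of agent i's belief about agent k (self included)."""
    return np.array([[beta_mean(b) for b in a.beliefs] for a in pop.agents])


def self_esteems(pop: Population) -> np.ndarray:
    return np.array([beta_mean(a.beliefs[a.index]) for a in pop.agents])


def informedness(belief_means: np.ndarray, honesties: np.ndarray) -> float:
    """Alignment of one agent's centered belief vector with the truth."""
    return float(np.dot(np.asarray(belief_means) - 0.5, np.asarray(honesties) - 0.5))


def informedness_all(pop: Population) -> np.ndarray:
    m = belief_mean_matrix(pop) - 0.5
    return m @ (pop.honesties - 0.5)


def agreement(belief_means_i: np.ndarray, belief_means_j: np.ndarray) -> float:
    """Alignment of two agents' centered belief vectors; symmetric."""
    return float(
        np.dot(np.asarray(belief_means_i) - 0.5, np.asarray(belief_means_j) - 0.5)
    )


def agreement_matrix(pop: Population) -> np.ndarray:
    c = belief_mean_matrix(pop) - 0.5
    return c @ c.T


def mean_agreement_with_others(pop: Population) -> np.ndarray:
    """Average agreement of each agent with every other agent."""
    a = agreement_matrix(pop)
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1) / (pop.n - 1)


@dataclass(frozen=True)
class NeighborhoodStats:
    neighborhood_honesty: float     # conversation-weighted true honesty of neighbors
    neighborhood_reputation: float  # reputation of the agent within its neighborhood
    over_under: float               # neighborhood reputation minus true honesty


def neighborhood_stats(pop: Population, i: int) -> Optional[NeighborhoodStats]:
    """Statistics of agent i's neighborhood (agents with >= 1 conversation).

    Returns ``None`` when the neighborhood is empty; such agents are
    excluded from aggregates.
    """
    convs = pop.agents[i].convs
    neighbors = np.flatnonzero(convs >= 1)
    if neighbors.size == 0:
        return None
    weights = convs[neighbors].astype(float)
    honesty = float(np.dot(weights, pop.honesties[neighbors]) / weights.sum())
    rep = combined_reputation([pop.agents[int(j)].beliefs[i] for j in neighbors])
    return NeighborhoodStats(honesty, rep, rep - pop.agents[i].traits.honesty)


def group_sizes(pop: Population, threshold: int = 100) -> np.ndarray:
    """Per-agent number of partners with at least ``threshold`` conversations."""
    return np.array([int((a.convs >= threshold).sum()) for a in pop.agents])


def surprise_histogram(values: Iterable[float], bins: np.ndarray) -> np.ndarray:
    """Histogram of realized surprises; overflow (including infinite
    surprises from maximally wrong certainty) lands in the last bin."""
    bins = np.asarray(bins, dtype=float)
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return np.zeros(len(bins) - 1, dtype=int)
    v = np.clip(v, bins[0], bins[-1])
    counts, _ = np.histogram(v, bins=bins)
    return counts


# -- ensemble-level curves ----------------------------------------------


def reputation_curve(results: Sequence[RealizationResult]) -> pd.DataFrame:
    """Mean final reputation per honesty grid point across realizations.

    Assumes the honesty grid is identical in every realization (the
    even-grid scheme guarantees this)."""
    honesties = results[0].population.honesties
    reps = np.array([all_reputations(r.population) for r in results])
    return pd.DataFrame(
        {
            "honesty": honesties,
            "mean_reputation": reps.mean(axis=0),
            "std_reputation": reps.std(axis=0),
        }
    )


def identity_crossings(honesty: np.ndarray, reputation: np.ndarray) -> List[float]:
    """Honesty values where the reputation curve crosses the identity line
    from above (overrated -> underrated), by linear interpolation."""
    h = np.asarray(honesty, dtype=float)
    d = np.asarray(reputation, dtype=float) - h
    crossings = []
    for i in range(len(h) - 1):
        if d[i] > 0.0 >= d[i + 1]:
            t = d[i] / (d[i] - d[i + 1])
            crossings.append(float(h[i] + t * (h[i + 1] - h[i])))
    return crossings


def reputation_crossing(results: Sequence[RealizationResult]) -> float:
    """Boundary honesty between net overestimation and net underestimation:
    the median identity crossing of the ensemble-mean reputation curve."""
    curve = reputation_curve(results)
    crossings = identity_crossings(
        curve["honesty"].to_numpy(), curve["mean_reputation"].to_numpy()
    )
    if not crossings:
        raise ValueError("reputation curve never crosses the identity line")
    return float(np.median(crossings))


def mean_group_size(results: Sequence[RealizationResult], threshold: int = 100) -> float:
    """Partners with >= threshold conversations, averaged over agents and
    realizations."""
    return float(
        np.mean([group_sizes(r.population, threshold).mean() for r in results])
    )


def agent_table(result: RealizationResult) -> pd.DataFrame:
    """Tidy per-agent metrics for one realization."""
    pop = result.population
    reps = all_reputations(pop)
    inf = informedness_all(pop)
    agree = mean_agreement_with_others(pop)
    esteem = self_esteems(pop)
    nbh = [neighborhood_stats(pop, i) for i in range(pop.n)]
    return pd.DataFrame(
        {
            "realization": result.realization,
            "agent": np.arange(pop.n),
            "honesty": pop.honesties,
            "reputation": reps,
            "self_esteem": esteem,
            "informedness": inf,
            "mean_agreement": agree,
            "neighborhood_honesty": [s.neighborhood_honesty if s else np.nan for s in nbh],
            "neighborhood_reputation": [
                s.neighborhood_reputation if s else np.nan for s in nbh
            ],
            "over_under": [s.over_under if s else np.nan for s in nbh],
            "group_size": group_sizes(pop),
        }
    )


def ensemble_table(results: Sequence[RealizationResult]) -> pd.DataFrame:
    return pd.concat([agent_table(r) for r in results], ignore_index=True)
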