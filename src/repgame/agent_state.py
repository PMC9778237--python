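"""Per-agent hidden traits, belief stores, theory of mind and ledgers.

Each agent carries

* immutable ground-truth traits (honesty x, shyness S, friendship
  affinity F) that it never reads when judging others — honesty is only
  consulted by the agent itself when deciding whether to lie;
* a belief book: one ``BeliefState`` per agent in the population,
  including itself (self-esteem);
* a theory of mind: an estimate of what every other agent believes
  about every agent;
* acquaintance ledgers (messages heard about each agent, conversations
  had with each agent), friendship ledgers (comparatively positive vs
  negative statements others made about the owner) and adaptive
  surprise scales that encode the perceived social climate.

All counters are monotone within a realization; traits never change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .beta_math import BeliefState

#: default weight of a conversation relative to a heard message in acquaintance
DEFAULT_CONVERSATION_WEIGHT = 10.0

#: initial value of the adaptive surprise scales (nat)
DEFAULT_INITIAL_SCALE = 1.0

#: lower floor for the surprise scales
SCALE_FLOOR = 1e-3


@dataclass(frozen=True)
class AgentTraits:
    """Ground-truth personality: honesty x, shyness S, friendship affinity F.

    All three live in [0, 1].  ``honesty`` is the per-statement
    probability of telling the truth; ``shyness`` exponentiates
    acquaintance in partner/topic choice; ``friendship_affinity``
    exponentiates friendship in partner choice.
    """

    honesty: float
    shyness: float
    friendship_affinity: float

    def __post_init__(self) -> None:
        for name in ("honesty", "shyness", "friendship_affinity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


class Agent:
    """Mutable per-agent state for one realization."""

    __slots__ = (
        "index",
        "traits",
        "q",
        "beliefs",
        "tom",
        "msgs_heard",
        "convs",
        "self_topic_convs",
        "positive",
        "negative",
        "_self_stmt_sum",
        "_self_stmt_count",
        "kappa_h",
        "kappa_nh",
        "kappa_lie",
        "last_heard",
    )

    def __init__(self, index: int, traits: AgentTraits, n: int,
                 q: float = DEFAULT_CONVERSATION_WEIGHT,
                 initial_scale: float = DEFAULT_INITIAL_SCALE) -> None:
        self.index = index
        self.traits = traits
        self.q = q
        # belief book: entry j is the belief about agent j's honesty
        self.beliefs: List[BeliefState] = [BeliefState(0.0, 0.0) for _ in range(n)]
        # theory of mind: tom[b][c] is the estimate of b's belief about c
        self.tom: List[List[BeliefState]] = [
            [BeliefState(0.0, 0.0) for _ in range(n)] for _ in range(n)
        ]
        self.msgs_heard = np.zeros(n, dtype=np.int64)   # r^m, per topic agent
        self.convs = np.zeros(n, dtype=np.int64)        # r^c, per partner
        self.self_topic_convs = 0                       # conversations about oneself
        self.positive = np.zeros(n, dtype=np.int64)     # pi, per speaker
        self.negative = np.zeros(n, dtype=np.int64)     # nu, per speaker
        self._self_stmt_sum = 0.0
        self._self_stmt_count = 0
        self.kappa_h = initial_scale
        self.kappa_nh = initial_scale
        self.kappa_lie = initial_scale
        self.last_heard: dict = {}  # (speaker, topic) -> BeliefState

    # -- friendship / acquaintance -------------------------------------

    def friendship(self, j: int) -> float:
        """Laplace-smoothed rate of comparatively positive statements from j."""
        p = self.positive[j]
        nneg = self.negative[j]
        return (p + 1.0) / (p + nneg + 2.0)

    def acquaintance(self, j: int) -> float:
        """r = r^m + Q r^c; for the owner itself, conversations in which
        it was the topic stand in for conversations with itself."""
        if j == self.index:
            return float(self.msgs_heard[j]) + self.q * self.self_topic_convs
        return float(self.msgs_heard[j]) + self.q * float(self.convs[j])

    def friendship_vector(self) -> np.ndarray:
        return (self.positive + 1.0) / (self.positive + self.negative + 2.0)

    def acquaintance_vector(self) -> np.ndarray:
        r = self.msgs_heard + self.q * self.convs
        r = r.astype(np.float64)
        r[self.index] = self.msgs_heard[self.index] + self.q * self.self_topic_convs
        return r

    # -- self-statement bookkeeping ------------------------------------

    @property
    def self_statement_mean(self) -> float:
        """Running mean of statement means heard about oneself (0.5 if none)."""
        if self._self_stmt_count == 0:
            return 0.5
        return self._self_stmt_sum / self._self_stmt_count

    def record_self_statement(self, speaker: int, statement_mean: float) -> None:
        """Classify a statement about oneself as comparatively positive or
        negative against the running mean of past statement means, then
        fold it into the running mean."""
        if statement_mean > self.self_statement_mean:
            self.positive[speaker] += 1
        else:
            self.negative[speaker] += 1
        self._self_stmt_sum += statement_mean
        self._self_stmt_count += 1


class Population:
    """All agents of one realization plus shared constants."""

    def __init__(self, agents: List[Agent], q: float) -> None:
        self.agents = agents
        self.n = len(agents)
        self.q = q

    @property
    def honesties(self) -> np.ndarray:
        return np.array([a.traits.honesty for a in self.agents])


def even_grid_honesties(n: int) -> np.ndarray:
    """Honesties i/(n-1), i = 0..n-1: an even grid covering [0, 1]."""
    return np.arange(n) / (n - 1)


def init_population(
    n: int,
    honesty_scheme: str = "even_grid",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    honesties: Optional[Sequence[float]] = None,
    q: float = DEFAULT_CONVERSATION_WEIGHT,
    initial_scale: float = DEFAULT_INITIAL_SCALE,
) -> Population:
    """Create a fresh population.

    Honesties follow the even grid i/(n-1) (``even_grid``) or an explicit
    list (``explicit``); shyness and friendship affinity are drawn
    uniformly on [0, 1] from the seeded generator.  Every belief and
    theory-of-mind entry starts at the uniform prior (0, 0), all ledgers
    at zero, the surprise scales at ``initial_scale``.
    """
    if n < 2:
        raise ValueError("population needs at least 2 agents")
    if rng is None:
        rng = np.random.default_rng(seed)
    if honesty_scheme == "even_grid":
        x = even_grid_honesties(n)
    elif honesty_scheme == "explicit":
        if honesties is None or len(honesties) != n:
            raise ValueError("explicit honesty scheme needs a list of length n")
        x = np.asarray(honesties, dtype=float)
        if np.any(x < 0.0) or np.any(x > 1.0):
            raise ValueError("honesties must lie in [0, 1]")
    else:
        raise ValueError(f"unknown honesty scheme: {honesty_scheme!r}")
    shyness = rng.random(n)
    affinity = rng.random(n)
    agents = [
        Agent(
            i,
            AgentTraits(float(x[i]), float(shyness[i]), float(affinity[i])),
            n,
            q=q,
            initial_scale=initial_scale,
        )
        for i in range(n)
    ]
    return Population(agents, q)


# -- snapshot serialization --------------------------------------------


def population_to_frames(pop: Population) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular snapshot: one row per ordered (owner, subject) pair plus a
    per-agent table of traits and scales."""
    rows = []
    for a in pop.agents:
        for j in range(pop.n):
            b = a.beliefs[j]
            rows.append(
                (
                    a.index,
                    j,
                    b.mu,
                    b.lam,
                    int(a.msgs_heard[j]),
                    int(a.convs[j]),
                    int(a.positive[j]),
                    int(a.negative[j]),
                )
            )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "owner",
            "subject",
            "mu",
            "lam",
            "messages_heard",
            "conversations",
            "positive",
            "negative",
        ],
    )
    agents = pd.DataFrame(
        {
            "agent": [a.index for a in pop.agents],
            "honesty": [a.traits.honesty for a in pop.agents],
            "shyness": [a.traits.shyness for a in pop.agents],
            "friendship_affinity": [a.traits.friendship_affinity for a in pop.agents],
            "kappa_h": [a.kappa_h for a in pop.agents],
            "kappa_nh": [a.kappa_nh for a in pop.agents],
            "kappa_lie": [a.kappa_lie for a in pop.agents],
            "self_topic_convs": [a.self_topic_convs for a in pop.agents],
            "self_statement_mean": [a.self_statement_mean for a in pop.agents],
        }
    )
    return pairs, agents


def save_snapshot(pop: Population, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pairs, agents = population_to_frames(pop)
    pairs.to_csv(d / "beliefs.csv", index=False)
    agents.to_csv(d / "agents.csv", index=False)


def load_snapshot(directory) -> Tuple[pd.DataFrame, pd.DataFrame]:
    from pathlib import Path

    d = Path(directory)
    return pd.read_csv(d / "beliefs.csv"), pd.read_csv(d / "agents.csv")
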