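"""Speaker side of a conversation: recipients, topic, honesty, message.

Partner choice weights are r_ab**S_a * f_ab**F_a (acquaintance and
friendship, exponentiated by the speaker's shyness and friendship
affinity); topic choice weights are r_ac**S_a over all agents including
the speaker itself.  A dishonest message starts from the speaker's
theory-of-mind estimate of the audience's opinion on the topic (a
weighted mixture compressed into one beta state) and is shifted by
|2 f_ac - 1| * Delta in the direction favoring the speaker, where Delta
is sized so that the unscaled shift would look exactly as surprising as
the speaker's learned typical surprise (its lie scale kappa_lie).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .agent_state import Agent, Population
from .beta_math import BeliefState, beta_mean, compress_weighted, kl_beta

ONE_TO_ONE = "one_to_one"
ONE_TO_MANY = "one_to_many"


@dataclass(frozen=True)
class ConversationPlan:
    initiator: int
    recipients: Tuple[int, ...]
    topic: int
    mode: str

    @property
    def n_recipients(self) -> int:
        return len(self.recipients)


@dataclass(frozen=True)
class AudienceProfile:
    """Normalized partner weights plus the merged audience opinion."""

    recipients: Tuple[int, ...]
    weights: Tuple[float, ...]
    merged_opinion: BeliefState


@dataclass(frozen=True)
class Message:
    payload: BeliefState
    speaker: int
    topic: int
    recipients: Tuple[int, ...]
    was_honest: bool  # ground truth; read only by the instrumentation layer
    blush: bool


def partner_weights(agent: Agent, pop: Population, track_acquaintance: bool = True) -> np.ndarray:
    """Unnormalized probability of addressing each agent (zero for self).

    With acquaintance tracking off (small-population mode) every other
    agent is equally likely.
    """
    n = pop.n
    if not track_acquaintance:
        w = np.ones(n)
    else:
        r = agent.acquaintance_vector()
        f = agent.friendship_vector()
        # 0**0 == 1: a zero exponent always means indifference
        w = r ** agent.traits.shyness * f ** agent.traits.friendship_affinity
    w[agent.index] = 0.0
    return w


def topic_weights(agent: Agent, pop: Population, track_acquaintance: bool = True) -> np.ndarray:
    """Unnormalized topic probabilities r_ac**S_a over all agents (self included)."""
    if not track_acquaintance:
        return np.ones(pop.n)
    r = agent.acquaintance_vector()
    return r ** agent.traits.shyness


def _sample(weights: np.ndarray, rng: np.random.Generator, size: int = 1,
            replace: bool = True) -> np.ndarray:
    """Sample indices proportional to ``weights``; uniform fallback when all
    weights vanish (cold start)."""
    total = weights.sum()
    if total <= 0.0:
        p = np.ones_like(weights) / len(weights)
    else:
        p = weights / total
    return rng.choice(len(weights), size=size, replace=replace, p=p)


def sample_n_recipients(agent: Agent, n: int, rng: np.random.Generator) -> int:
    """Broadcast size N_b drawn proportional to N_b**(-S_a) on {2, ..., n-1}."""
    ks = np.arange(2, n, dtype=float)
    w = ks ** (-agent.traits.shyness)
    return int(rng.choice(ks, p=w / w.sum()))


def choose_recipients(
    agent: Agent,
    pop: Population,
    rng: np.random.Generator,
    one_to_many_prob: float = 0.5,
    track_acquaintance: bool = True,
) -> Tuple[str, Tuple[int, ...]]:
    """Draw the conversation mode and the recipient set.

    The one-to-one / one-to-many split is a fair coin by default and
    deliberately independent of shyness; populations of two agents can
    only hold one-to-one conversations.
    """
    broadcast = pop.n > 2 and rng.random() < one_to_many_prob
    w = partner_weights(agent, pop, track_acquaintance)
    if w.sum() <= 0.0:
        # cold start: uniform over the other agents, never over oneself
        w = np.ones(pop.n)
        w[agent.index] = 0.0
    if not broadcast:
        b = int(_sample(w, rng)[0])
        return ONE_TO_ONE, (b,)
    n_b = sample_n_recipients(agent, pop.n, rng)
    # cold start: if fewer than n_b agents have positive weight, the
    # uniform fallback still has full support
    if np.count_nonzero(w) < n_b:
        w = np.ones(pop.n)
        w[agent.index] = 0.0
    recipients = _sample(w, rng, size=n_b, replace=False)
    return ONE_TO_MANY, tuple(int(i) for i in recipients)


def choose_topic(
    agent: Agent,
    pop: Population,
    rng: np.random.Generator,
    track_acquaintance: bool = True,
) -> int:
    return int(_sample(topic_weights(agent, pop, track_acquaintance), rng)[0])


def decide_honest(agent: Agent, rng: np.random.Generator) -> bool:
    """Bernoulli(x_a) per statement."""
    return rng.random() < agent.traits.honesty


def merge_audience_opinion(
    agent: Agent,
    recipients: Sequence[int],
    topic: int,
    compression: str = "kl_optimal",
    track_acquaintance: bool = True,
) -> AudienceProfile:
    """Blend the theory-of-mind opinions of all recipients about the topic.

    Weights are the partner-choice weights restricted to the audience
    (uniform on a cold start); the weighted mixture is compressed with
    the same method the receivers use.  A single recipient returns its
    theory-of-mind entry exactly.
    """
    recipients = tuple(recipients)
    comps = [agent.tom[i][topic] for i in recipients]
    if len(recipients) == 1:
        return AudienceProfile(recipients, (1.0,), comps[0])
    if track_acquaintance:
        w = np.array(
            [
                agent.acquaintance(i) ** agent.traits.shyness
                * agent.friendship(i) ** agent.traits.friendship_affinity
                for i in recipients
            ]
        )
    else:
        w = np.ones(len(recipients))
    if w.sum() <= 0.0:
        w = np.ones(len(recipients))
    w = w / w.sum()
    merged = compress_weighted(w, comps, method=compression)
    return AudienceProfile(recipients, tuple(float(x) for x in w), merged)


def lie_shift(base: BeliefState, kappa: float, direction: str) -> float:
    """Unscaled lie magnitude Delta.

    Delta is the unique positive shift of ``base`` (on mu for a positive
    lie, on lam for a negative one) whose KL divergence from ``base``
    equals ``kappa`` — the lie is made exactly as surprising as the
    social climate says lies typically are.  Found by bracketed root
    finding on the monotone map Delta -> KL.

    The magnitude is capped at two orders of magnitude more pseudo-counts
    than the base state carries: near-degenerate bases (lam close to -1
    with large mu) make the KL grow so slowly in Delta that the nominal
    solution would be astronomical, which models nothing.
    """
    if kappa <= 0.0:
        return 0.0
    cap = 100.0 * (base.mu + base.lam + 2.0) + 100.0

    if direction == "positive":
        def g(d: float) -> float:
            return kl_beta(base.shifted(d_mu=d), base) - kappa
    elif direction == "negative":
        def g(d: float) -> float:
            return kl_beta(base.shifted(d_lam=d), base) - kappa
    else:
        raise ValueError(f"no shift for direction {direction!r}")

    hi = 1.0
    while g(hi) < 0.0:
        hi *= 2.0
        if hi >= cap:
            return cap
    return float(brentq(g, 0.0, hi, rtol=1e-10, maxiter=200))


def construct_message(
    agent: Agent,
    plan: ConversationPlan,
    honest: bool,
    rng: np.random.Generator,
    compression: str = "kl_optimal",
    blush_rate: float = 0.1,
    track_acquaintance: bool = True,
) -> Message:
    """Build the outgoing message.

    Honest: the payload is the speaker's own belief about the topic.
    Dishonest: start from the merged audience opinion; lie positively
    about friends (f_ac > 1/2) and about oneself (pretending f_aa = 1),
    negatively about enemies, not at all when f_ac = 1/2 (white lie);
    the shift is |2 f_ac - 1| * Delta with Delta from ``lie_shift``.
    Lies blush with probability ``blush_rate``.
    """
    c = plan.topic
    if honest:
        return Message(agent.beliefs[c], agent.index, c, plan.recipients, True, False)

    profile = merge_audience_opinion(
        agent, plan.recipients, c, compression, track_acquaintance
    )
    base = profile.merged_opinion
    if c == agent.index:
        factor = 1.0  # agents pretend f_aa = 1 about themselves
        direction = "positive"
    else:
        f = agent.friendship(c)
        factor = abs(2.0 * f - 1.0)
        if f > 0.5:
            direction = "positive"
        elif f < 0.5:
            direction = "negative"
        else:
            direction = "white"
    if direction == "white" or factor == 0.0:
        payload = base
    else:
        delta = factor * lie_shift(base, agent.kappa_lie, direction)
        if direction == "positive":
            payload = base.shifted(d_mu=delta)
        else:
            payload = base.shifted(d_lam=delta)
    blush = bool(rng.random() < blush_rate)
    return Message(payload, agent.index, c, plan.recipients, False, blush)


def predicted_credibility(agent: Agent, recipient: int, msg: Message,
                          epsilon: float = 1e-6) -> float:
    """Credibility the speaker expects ``recipient`` to assign, evaluated
    from the speaker's theory of mind and its own surprise scales."""
    from .reception import bayes_credibility, surprise_likelihood_ratio

    xbar = beta_mean(agent.tom[recipient][agent.index])
    if msg.blush:
        return 0.0
    if msg.topic == agent.index and beta_mean(msg.payload) < xbar:
        return 1.0
    s = kl_beta(msg.payload, agent.tom[recipient][msg.topic])
    log_r = surprise_likelihood_ratio(
        s, agent.kappa_h, agent.kappa_nh, agent.kappa_lie
    )
    return bayes_credibility(xbar, log_r, epsilon)


def speaker_postprocess(
    agent: Agent,
    msg: Message,
    pop: Population,
    epsilon: float = 1e-6,
    count_conversation: bool = True,
) -> None:
    """After sending: blend the speaker's theory of mind of each recipient
    toward the sent payload (weighted by the credibility the speaker
    predicts the recipient assigns) and credit the conversation ledgers."""
    for b in msg.recipients:
        y = predicted_credibility(agent, b, msg, epsilon)
        prior = agent.tom[b][msg.topic]
        agent.tom[b][msg.topic] = BeliefState(
            y * msg.payload.mu + (1.0 - y) * prior.mu,
            y * msg.payload.lam + (1.0 - y) * prior.lam,
        )
        if count_conversation:
            agent.convs[b] += 1
    if count_conversation and msg.topic == agent.index:
        agent.self_topic_convs += len(msg.recipients)
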