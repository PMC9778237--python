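"""Receiver side: credibility judgment, knowledge updates, adaptation.

A received message is processed in a fixed order:

1. ``assess_credibility`` — Bayes with the speaker's reputation as prior
   and a surprise-based likelihood ratio, overridden by the two certain
   cues (blushing => lie, confession => honest);
2. ``update_on_speaker`` — the belief about the speaker becomes the
   compressed mixture of "one more honest statement" and "one more lie";
3. ``update_tom`` — DeGroot-style blend of the theory of mind toward the
   payload;
4. ``novelty`` — clip the payload against the speaker's last statement
   on the topic so repeated opinions carry no new information;
5. ``update_on_topic`` — the belief about the topic becomes the
   compressed mixture of "accept the novel part" and "ignore it";
6. ``adapt_scales_and_ledgers`` — exponential moving averages of the
   surprise split by judged honesty, plus ledger increments.

Permuting the assessment after any update would change results; the
order is part of the model contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .agent_state import Agent, SCALE_FLOOR
from .beta_math import (
    BeliefState,
    beta_mean,
    cap_evidence,
    compress_weighted,
    kl_beta,
)

#: default evidence capacity of one belief entry (total pseudo-counts)
DEFAULT_BELIEF_CAPACITY = 300.0

#: at most this many pseudo-counts of topic evidence per statement
STATEMENT_EVIDENCE = 1.0
from .conversation import Message

CUE_NONE = "none"
CUE_BLUSH = "blush"
CUE_CONFESSION = "confession"


@dataclass(frozen=True)
class CredibilityAssessment:
    credibility: float
    likelihood_ratio: float
    speaker_reputation: float
    surprise_observed: float  # KL of payload vs the receiver's belief on the topic
    cue: str


@dataclass(frozen=True)
class NoveltyIncrement:
    d_mu: float
    d_lam: float


@dataclass(frozen=True)
class SurpriseRecord:
    credibility: float
    actually_honest: bool
    surprise: float


def surprise_likelihood_ratio(
    s: float, kappa_h: float, kappa_nh: float, kappa_lie: float
) -> float:
    """log R(d) under exponential surprise models for the two hypotheses.

    ``kappa_h`` is the adaptive social-climate scale: the typical
    surprise a message carries around here.  An honest message is
    modelled as Exp(kappa_h).  A lie is a shifted version of an
    otherwise plausible opinion, and the lying strategy itself sizes the
    shift at a climate-sized KL (``kappa_lie``), so a lie's surprise
    carries the honest baseline plus the typical lie on top: scale
    ``scale_nh = max(kappa_nh, kappa_h + kappa_lie)``, where
    ``kappa_nh`` additionally tracks the surprises of messages judged
    dishonest (it exceeds the floor in toxic climates):

        R(d) = [kappa_h^-1 exp(-s/kappa_h)]
             / [scale_nh^-1 exp(-s/scale_nh)].

    ln R falls monotonically in s and crosses zero at an adaptive
    threshold of about 1.4 kappa_h: messages near the typical surprise
    pass, messages deviating far beyond it are suspect.  Returns ln R.
    """
    scale_nh = max(kappa_nh, kappa_h + kappa_lie)
    return math.log(scale_nh) - math.log(kappa_h) + s * (1.0 / scale_nh - 1.0 / kappa_h)


def bayes_credibility(xbar: float, log_r: float, epsilon: float = 1e-6) -> float:
    """Posterior probability of honesty from prior ``xbar`` and ln R(d),
    clipped into [epsilon, 1 - epsilon] so surprises stay finite."""
    # y = xbar R / (xbar R + 1 - xbar), computed via exp(-ln R) for stability
    t = -log_r + math.log1p(-xbar) - math.log(xbar)
    if t > 700.0:
        y = 0.0
    elif t < -700.0:
        y = 1.0
    else:
        y = 1.0 / (1.0 + math.exp(t))
    return min(max(y, epsilon), 1.0 - epsilon)


def assess_credibility(agent: Agent, msg: Message, epsilon: float = 1e-6) -> CredibilityAssessment:
    """Judge how credible a message is, before any state is updated.

    Blushing forces credibility 0; a confession (self-referential message
    strictly more negative than the receiver's current view of the
    speaker) forces credibility 1; otherwise Bayes combines the speaker's
    reputation with the surprise likelihood ratio.
    """
    a = msg.speaker
    xbar = beta_mean(agent.beliefs[a])
    s = kl_beta(msg.payload, agent.beliefs[msg.topic])
    if msg.blush:
        return CredibilityAssessment(0.0, 0.0, xbar, s, CUE_BLUSH)
    if msg.topic == a and beta_mean(msg.payload) < xbar:
        return CredibilityAssessment(1.0, math.inf, xbar, s, CUE_CONFESSION)
    log_r = surprise_likelihood_ratio(
        s, agent.kappa_h, agent.kappa_nh, agent.kappa_lie
    )
    y = bayes_credibility(xbar, log_r, epsilon)
    ratio = math.exp(log_r) if log_r < 700.0 else math.inf
    return CredibilityAssessment(y, ratio, xbar, s, CUE_NONE)


def update_on_speaker(agent: Agent, speaker: int, y: float,
                      compression: str = "kl_optimal",
                      capacity: float = DEFAULT_BELIEF_CAPACITY) -> BeliefState:
    """Belief about the speaker: compressed mixture of one extra honest
    count (weight y) and one extra dishonest count (weight 1-y), clipped
    to the evidence capacity."""
    mu, lam = agent.beliefs[speaker]
    new = cap_evidence(
        compress_weighted(
            (y, 1.0 - y),
            (BeliefState(mu + 1.0, lam), BeliefState(mu, lam + 1.0)),
            method=compression,
        ),
        capacity,
    )
    agent.beliefs[speaker] = new
    return new


def update_tom(agent: Agent, speaker: int, topic: int, y: float,
               payload: BeliefState) -> BeliefState:
    """Theory of mind about (speaker, topic): componentwise convex blend
    toward the payload with weight y (DeGroot-style, no compression)."""
    prior = agent.tom[speaker][topic]
    new = BeliefState(
        y * payload.mu + (1.0 - y) * prior.mu,
        y * payload.lam + (1.0 - y) * prior.lam,
    )
    agent.tom[speaker][topic] = new
    return new


def novelty(agent: Agent, speaker: int, topic: int,
            payload: BeliefState) -> NoveltyIncrement:
    """Apparent new information relative to the speaker's last statement
    on the topic: componentwise clipped difference.  Repeating the same
    opinion contributes nothing.  Updates the last-heard ledger."""
    prev = agent.last_heard.get((speaker, topic))
    if prev is None:
        inc = NoveltyIncrement(max(0.0, payload.mu), max(0.0, payload.lam))
    else:
        inc = NoveltyIncrement(
            max(0.0, payload.mu - prev.mu), max(0.0, payload.lam - prev.lam)
        )
    agent.last_heard[(speaker, topic)] = payload
    return inc


def update_on_topic(agent: Agent, topic: int, y: float, inc: NoveltyIncrement,
                    compression: str = "kl_optimal",
                    capacity: float = DEFAULT_BELIEF_CAPACITY) -> BeliefState:
    """Belief about the topic: compressed mixture of accepting the novel
    increment (weight y) and keeping the prior (weight 1-y).

    One statement is worth at most one pseudo-observation: the novelty
    increment keeps its direction but its total is clipped to
    ``STATEMENT_EVIDENCE``.  A message is a claim, not a data set —
    without this bound a payload fattened by everything its speaker ever
    heard would be absorbed wholesale, and opinions circulating along
    loops (a tells b, b tells c, c tells a) would re-amplify
    exponentially.  The resulting belief is clipped to the evidence
    capacity."""
    total = inc.d_mu + inc.d_lam
    if total > STATEMENT_EVIDENCE:
        f = STATEMENT_EVIDENCE / total
        inc = NoveltyIncrement(inc.d_mu * f, inc.d_lam * f)
    mu, lam = agent.beliefs[topic]
    new = cap_evidence(
        compress_weighted(
            (y, 1.0 - y),
            (BeliefState(mu + inc.d_mu, lam + inc.d_lam), BeliefState(mu, lam)),
            method=compression,
        ),
        capacity,
    )
    agent.beliefs[topic] = new
    return new


def record_surprise(y: float, actually_honest: bool) -> SurpriseRecord:
    """Realized surprise -ln p(true outcome); instrumentation only, never
    fed back into agent state."""
    p = y if actually_honest else 1.0 - y
    s = -math.log(p) if p > 0.0 else math.inf
    return SurpriseRecord(y, actually_honest, s)


def adapt_scales_and_ledgers(
    agent: Agent,
    msg: Message,
    assessment: CredibilityAssessment,
    ema_alpha: float = 0.1,
    count_conversation: bool = True,
) -> None:
    """Adapt the social-climate scales and the acquaintance/friendship
    ledgers after a judged message.

    The climate scale kappa_h tracks the *typical* surprise of the
    messages an agent hears, whatever their honesty: a running median
    estimate, via multiplicative up/down steps, which the rare huge
    surprises that sharp disagreements produce cannot inflate the way
    they would inflate a mean.  It is deliberately unconditional on the
    credibility judgment: conditioning it would let early skepticism
    feed on itself — only small surprises would ever be accepted, the
    scale would deflate to the accepted bulk, and the population would
    lock into rejecting everything.  The dishonest scale kappa_nh
    tracks the surprises of messages judged dishonest with
    responsibility weight 1-y; it matters only in toxic climates, where
    it exceeds its kappa_h + kappa_lie floor.
    """
    y = assessment.credibility
    s = assessment.surprise_observed
    if s > agent.kappa_h:
        agent.kappa_h = agent.kappa_h * (1.0 + ema_alpha)
    else:
        agent.kappa_h = max(SCALE_FLOOR, agent.kappa_h / (1.0 + ema_alpha))
    agent.kappa_nh = max(
        SCALE_FLOOR,
        (1.0 - ema_alpha * (1.0 - y)) * agent.kappa_nh + ema_alpha * (1.0 - y) * s,
    )
    agent.kappa_lie = agent.kappa_h  # perceived climate sets the own lie size
    agent.msgs_heard[msg.topic] += 1
    if count_conversation:
        agent.convs[msg.speaker] += 1
        if msg.topic == agent.index:
            agent.self_topic_convs += 1
    if msg.topic == agent.index:
        agent.record_self_statement(msg.speaker, beta_mean(msg.payload))


def receive_message(
    agent: Agent,
    msg: Message,
    compression: str = "kl_optimal",
    epsilon: float = 1e-6,
    ema_alpha: float = 0.1,
    count_conversation: bool = True,
    capacity: float = DEFAULT_BELIEF_CAPACITY,
) -> CredibilityAssessment:
    """Full fixed-order reception pipeline for one message."""
    assessment = assess_credibility(agent, msg, epsilon)
    y = assessment.credibility
    update_on_speaker(agent, msg.speaker, y, compression, capacity)
    update_tom(agent, msg.speaker, msg.topic, y, msg.payload)
    inc = novelty(agent, msg.speaker, msg.topic, msg.payload)
    update_on_topic(agent, msg.topic, y, inc, compression, capacity)
    adapt_scales_and_ledgers(agent, msg, assessment, ema_alpha, count_conversation)
    return assessment
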