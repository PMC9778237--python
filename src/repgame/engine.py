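"""Simulation driver: rounds, answers, RNG discipline, artifacts.

Every round iterates the agents in fixed index order; each agent
initiates one conversation (a fair coin decides between one-to-one and
broadcast).  One-to-one initiations are answered on the same topic with
a fresh honesty draw; broadcasts are one-way.  All randomness flows
through a single ``numpy`` generator per realization, seeded from
``(config.seed, realization_index)``, so reruns are byte-identical and
individual realizations can be reproduced in isolation.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .agent_state import Population, init_population, save_snapshot
from .conversation import (
    ONE_TO_ONE,
    ConversationPlan,
    choose_recipients,
    choose_topic,
    construct_message,
    decide_honest,
    speaker_postprocess,
)
from .reception import receive_message, record_surprise

COMPRESSIONS = ("kl_optimal", "moment_matching")

#: keys every event record must carry, by kind (schema for validation)
EVENT_SCHEMA = {
    "message": {
        "round": int,
        "kind": str,
        "speaker": int,
        "recipients": list,
        "topic": int,
        "mu": float,
        "lam": float,
        "honest": bool,
        "blush": bool,
        "answer": bool,
    },
    "reception": {
        "round": int,
        "kind": str,
        "receiver": int,
        "speaker": int,
        "topic": int,
        "credibility": float,
        "cue": str,
        "surprise_observed": float,
    },
}


@dataclass(frozen=True)
class Constants:
    """Behavioral constants of the model."""

    q: float = 10.0               # conversation weight in acquaintance
    blush_rate: float = 0.1       # lies blush on average once in ten
    ema_alpha: float = 0.1        # memory constant of the surprise scales
    epsilon: float = 1e-6         # credibility clipping (cue-free case)
    initial_scale: float = 1.0    # starting surprise scale (nat)
    one_to_many_prob: float = 0.5  # fair coin between the two modes
    belief_capacity: float = 300.0  # evidence memory per belief entry


@dataclass
class RunConfig:
    n_agents: int = 50
    n_rounds: int = 300
    n_realizations: int = 1
    compression: str = "kl_optimal"
    seed: int = 0
    honesty_scheme: str = "even_grid"
    honesties: Optional[List[float]] = None
    track_acquaintance: bool = True
    record_events: bool = False
    instrument: bool = False
    record_reputation_trajectory: bool = False
    constants: Constants = field(default_factory=Constants)
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_agents < 2 or self.n_rounds < 1 or self.n_realizations < 1:
            raise ValueError("counts must be positive (and n_agents >= 2)")
        if self.compression not in COMPRESSIONS:
            raise ValueError(f"compression must be one of {COMPRESSIONS}")
        if not (0.0 <= self.constants.blush_rate <= 1.0):
            raise ValueError("blush_rate must lie in [0, 1]")

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("constants"), dict):
            d["constants"] = Constants(**d["constants"])
        return cls(**d)


@dataclass
class RealizationResult:
    population: Population
    realization: int
    counters: Dict[str, int]
    events: Optional[List[dict]] = None
    surprises: Optional[List[List[float]]] = None
    reputation_trajectory: Optional[np.ndarray] = None


def realization_rng(seed: int, k: int) -> np.random.Generator:
    """Splittable per-realization generator: realization k depends only on
    (seed, k), so any single realization can be rerun in isolation."""
    return np.random.default_rng(np.random.SeedSequence((seed, k)))


def _deliver(pop, msg, receiver, cfg, counters, events, surprises, round_idx,
             count_conversation):
    c = cfg.constants
    assessment = receive_message(
        pop.agents[receiver],
        msg,
        compression=cfg.compression,
        epsilon=c.epsilon,
        ema_alpha=c.ema_alpha,
        count_conversation=count_conversation,
        capacity=c.belief_capacity,
    )
    counters["receptions"] += 1
    if surprises is not None:
        rec = record_surprise(assessment.credibility, msg.was_honest)
        surprises[receiver].append(rec.surprise)
    if events is not None:
        events.append(
            {
                "round": round_idx,
                "kind": "reception",
                "receiver": receiver,
                "speaker": msg.speaker,
                "topic": msg.topic,
                "credibility": assessment.credibility,
                "cue": assessment.cue,
                "surprise_observed": assessment.surprise_observed,
            }
        )
    return assessment


def _log_message(events, round_idx, msg, answer):
    if events is not None:
        events.append(
            {
                "round": round_idx,
                "kind": "message",
                "speaker": msg.speaker,
                "recipients": list(msg.recipients),
                "topic": msg.topic,
                "mu": msg.payload.mu,
                "lam": msg.payload.lam,
                "honest": msg.was_honest,
                "blush": msg.blush,
                "answer": answer,
            }
        )


def _count_message(counters, msg):
    counters["messages"] += 1
    if not msg.was_honest:
        counters["lies"] += 1
        if msg.blush:
            counters["blushes"] += 1


def run_round(pop: Population, cfg: RunConfig, rng: np.random.Generator,
              round_idx: int, counters: Dict[str, int],
              events: Optional[List[dict]] = None,
              surprises: Optional[List[List[float]]] = None) -> None:
    """One conversation round: every agent initiates once, in index order."""
    c = cfg.constants
    for a in range(pop.n):
        agent = pop.agents[a]
        mode, recipients = choose_recipients(
            agent, pop, rng, c.one_to_many_prob, cfg.track_acquaintance
        )
        topic = choose_topic(agent, pop, rng, cfg.track_acquaintance)
        plan = ConversationPlan(a, recipients, topic, mode)
        honest = decide_honest(agent, rng)
        msg = construct_message(
            agent, plan, honest, rng, cfg.compression, c.blush_rate,
            cfg.track_acquaintance,
        )
        _count_message(counters, msg)
        _log_message(events, round_idx, msg, answer=False)
        for b in recipients:
            _deliver(pop, msg, b, cfg, counters, events, surprises, round_idx,
                     count_conversation=True)
            counters["conversations"] += 1
        speaker_postprocess(agent, msg, pop, c.epsilon, count_conversation=True)
        if mode == ONE_TO_ONE:
            b = recipients[0]
            responder = pop.agents[b]
            answer_plan = ConversationPlan(b, (a,), topic, ONE_TO_ONE)
            honest2 = decide_honest(responder, rng)
            answer = construct_message(
                responder, answer_plan, honest2, rng, cfg.compression,
                c.blush_rate, cfg.track_acquaintance,
            )
            _count_message(counters, answer)
            _log_message(events, round_idx, answer, answer=True)
            # the answer belongs to the same conversation: no second
            # conversation credit, but it is a heard message like any other
            _deliver(pop, answer, a, cfg, counters, events, surprises,
                     round_idx, count_conversation=False)
            speaker_postprocess(responder, answer, pop, c.epsilon,
                                count_conversation=False)


def run_realization(cfg: RunConfig, k: int = 0) -> RealizationResult:
    """Run one realization with its own derived seed."""
    rng = realization_rng(cfg.seed, k)
    pop = init_population(
        cfg.n_agents,
        cfg.honesty_scheme,
        rng=rng,
        honesties=cfg.honesties,
        q=cfg.constants.q,
        initial_scale=cfg.constants.initial_scale,
    )
    events: Optional[List[dict]] = [] if cfg.record_events else None
    surprises = [[] for _ in range(pop.n)] if cfg.instrument else None
    counters = {
        "messages": 0,
        "conversations": 0,
        "lies": 0,
        "blushes": 0,
        "receptions": 0,
    }
    trajectory = [] if cfg.record_reputation_trajectory else None
    for r in range(cfg.n_rounds):
        run_round(pop, cfg, rng, r, counters, events, surprises)
        if trajectory is not None:
            from .metrics import all_reputations

            trajectory.append(all_reputations(pop))
    return RealizationResult(
        population=pop,
        realization=k,
        counters=counters,
        events=events,
        surprises=surprises,
        reputation_trajectory=np.array(trajectory) if trajectory is not None else None,
    )


def write_events(events: List[dict], path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps(e, sort_keys=True) + "\n")


def read_events(path) -> List[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def validate_event_log(events: List[dict]) -> None:
    """Raise ``ValueError`` on any record that violates the event schema."""
    for i, e in enumerate(events):
        kind = e.get("kind")
        schema = EVENT_SCHEMA.get(kind)
        if schema is None:
            raise ValueError(f"record {i}: unknown kind {kind!r}")
        for key, typ in schema.items():
            if key not in e:
                raise ValueError(f"record {i}: missing key {key!r}")
            v = e[key]
            if typ is float:
                if not isinstance(v, (int, float)) or isinstance(v, bool):
                    raise ValueError(f"record {i}: {key!r} must be numeric")
            elif typ is int:
                if not isinstance(v, int) or isinstance(v, bool):
                    raise ValueError(f"record {i}: {key!r} must be an integer")
            elif not isinstance(v, typ):
                raise ValueError(f"record {i}: {key!r} must be {typ.__name__}")


def run_realizations(cfg: RunConfig, progress: bool = False) -> List[RealizationResult]:
    """Run all realizations; write logs, snapshots and a manifest when an
    output directory is configured."""
    outdir = Path(cfg.outdir) if cfg.outdir else None
    results = []
    for k in range(cfg.n_realizations):
        res = run_realization(cfg, k)
        results.append(res)
        if outdir is not None:
            d = outdir / f"real_{k:03d}"
            d.mkdir(parents=True, exist_ok=True)
            save_snapshot(res.population, d)
            with open(d / "counters.json", "w") as fh:
                json.dump(res.counters, fh, indent=2, sort_keys=True)
            if res.events is not None:
                write_events(res.events, d / "events.jsonl")
            if res.surprises is not None:
                with open(d / "surprises.json", "w") as fh:
                    json.dump(res.surprises, fh)
        if progress:
            print(f"realization {k + 1}/{cfg.n_realizations} done", flush=True)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": cfg.to_dict(),
            "version": __version__,
            "realization_seeds": [[cfg.seed, k] for k in range(cfg.n_realizations)],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def load_manifest(outdir) -> RunConfig:
    with open(Path(outdir) / "manifest.json") as fh:
        manifest = json.load(fh)
    return RunConfig.from_dict(manifest["config"])
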