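# repgame

An agent-based simulator of gossip and reputation dynamics.  A population
of agents, each with a hidden per-statement honesty `x ∈ [0, 1]`, spends
rounds talking about one another's honesty.  Messages may be deceptive;
receivers judge each message's credibility by approximate Bayesian
inference with a rudimentary theory of mind, and — being boundedly
rational — compress the resulting mixture posteriors back into simple
beta-form beliefs.  The package is aimed at computational social
psychology / sociophysics work on emergent phenomena such as the
Cassandra syndrome (honest agents that are not believed), reputation
boosts from consistently maintained fake images, and the divergence
between being well-informed and being in agreement with others.

## Model in brief

Knowledge about one honesty value is a beta distribution
`P(x|I) ∝ x^μ (1−x)^λ`, with `(μ, λ)` acting as pseudo-counts of honest
and dishonest statements.  Each agent keeps such a state about every
agent (including itself — its self-esteem), plus a theory of mind
`I_abc`: what agent *a* thinks agent *b* believes about agent *c*.

Per round every agent initiates one conversation: partner(s) chosen with
probability `∝ r^S · f^F` (acquaintance `r = r^m + Q r^c`, friendship
`f = (π+1)/(π+ν+2)`, exponentiated by the speaker's shyness `S` and
friendship affinity `F`), topic chosen `∝ r^S`.  Honest speakers
transmit their belief; dishonest speakers start from the audience's
estimated opinion and shift it by `|2f−1| Δ` in the direction that
serves them, `Δ` sized so the lie looks exactly as surprising as the
learned social climate says messages typically are.  Lies blush with
probability 0.1.

A receiver judges credibility `y_J` by Bayes,

    y_J = R(d)·x̄ / (R(d)·x̄ + 1 − x̄),

with the speaker's reputation `x̄` as prior and a surprise likelihood
ratio `R(d)` built from adaptive climate scales (blushing forces
`y_J = 0`, a confession — a self-statement more negative than the
receiver's current view — forces `y_J = 1`).  It then mixes
"the message was honest" and "it was a lie" posteriors for the speaker
and the topic and compresses them back to beta form, either KL-optimally
(conserving `⟨ln x⟩` and `⟨ln(1−x)⟩`, solved by damped Newton on the
digamma system) or by moment matching (conserving mean and variance,
closed form).  Ensemble statistics include each agent's combined
reputation, informedness `Σ_k (x̄_ik − ½)(x_k − ½)`, pairwise agreement,
and conversation-weighted neighborhood summaries.

See `docs/methods.md` for the full account, including the design choices
made where the mechanism was genuinely open and the model's known
limitations.

## Worked example

```python
from repgame import RunConfig, run_realization
from repgame import metrics

cfg = RunConfig(n_agents=10, n_rounds=50, seed=42, record_events=True)
res = run_realization(cfg)
print(res.counters)
print(metrics.all_reputations(res.population).round(3))
print(metrics.informedness_all(res.population).round(2))
```

prints (the counters of one seeded run, then per-agent statistics)

```
{'messages': 756, 'conversations': 1388, 'lies': 360, 'blushes': 40, 'receptions': 1644}
[0.332 0.211 0.574 0.666 0.664 0.834 0.734 0.696 0.951 0.516]
[0.49 0.41 0.42 0.49 0.32 0.16 0.43 0.39 0.3  0.18]
```

The ten agents have true honesties 0, 1/9, …, 1.  After only 50 rounds
the population's combined view of each agent (`all_reputations`) is
noisy but already rises with true honesty — the two most dishonest
agents sit lowest (0.33, 0.21), the second-most-honest agent highest
(0.95) — and every agent has accumulated positive informedness, i.e., a
belief vector aligned with the hidden truth.  Of the 360 lies told, 40
blushed (the configured one-in-ten telltale).

The same is available from a shell:

```bash
repgame run --agents 10 --rounds 50 --seed 42 --outdir out/ --record-events
repgame metrics out/ --out tables/
repgame experiment three-agent --outdir exp3/   # compression comparison
repgame experiment fifty-agent --outdir exp50/  # full ensemble tables
```

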