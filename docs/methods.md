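# Model and methods

## Belief representation

Knowledge about one agent's honesty `x ∈ [0,1]` is a beta-form state
`P(x|I) ∝ x^μ (1−x)^λ` with exponents `(μ, λ)` acting as pseudo-counts of
honest and dishonest statements.  The joint belief over all agents is the
product of the per-agent states; no correlations are ever stored.  The
exponent domain is `(−1, ∞)`, not `[0, ∞)`: compressing a legitimate
mixture by moment matching can produce exponents in `(−1, 0)` (the
worked example `0.5·Beta(2,0) + 0.5·Beta(0,2)` compresses to
`(−0.25, −0.25)`), and clamping would silently break the conservation
contract.

## Belief compression

Updates produce two-component beta mixtures (and audience merging
produces N-component ones).  Bounded rationality forces them back into a
single beta state by one of two rules:

* **KL-optimal** — minimize `D_KL(mixture ‖ beta)`, equivalent to
  conserving `⟨ln x⟩` and `⟨ln(1−x)⟩`.  Implemented as a damped Newton
  iteration on the digamma system `ψ(μ″+1) − ψ(μ″+λ″+2) = ⟨ln x⟩`,
  `ψ(λ″+1) − ψ(μ″+λ″+2) = ⟨ln(1−x)⟩`, initialized at the moment-matching
  solution (near-exact for tight mixtures), with step halving until the
  residual norm decreases and the domain `μ, λ > −1` is respected.
  Tolerance 1e−10 (scaled up for targets far from O(1)), cap 200
  iterations, non-convergence raises.  The mixture log-moments are the
  weighted sums of the component closed forms (linearity of expectation);
  no quadrature in the hot path.
* **Moment matching** — conserve mean and variance:
  `s = mean(1−mean)/var − 1`, `μ″ = mean·s − 1`, `λ″ = (1−mean)·s − 1`.
  The mixture variance is computed in the shifted form
  `Σ w_i (var_i + (mean_i − mean)²)`, which is immune to the
  cancellation that `E[x²] − mean²` suffers for very sharp components.

Degenerate mixtures (one effective component) are returned exactly.  If
floating-point underflow produces a variance outside `(0, mean(1−mean))`
— impossible in exact arithmetic — the dominant component is returned,
being the answer to machine precision.

## Conversation mechanics

Each round, every agent initiates one conversation in fixed index order.
A fair coin picks one-to-one (answered on the same topic, with a fresh
honesty draw by the responder) or one-to-many (one-way; size
`∝ N^(−S)` on `{2, …, n−1}`).  Partner weights are `r^S f^F`
(acquaintance `r = r^m + Q·r^c` with `Q = 10`, Laplace-smoothed
friendship `f`), topic weights `r^S` over all agents including the
speaker (self-acquaintance counts messages heard about oneself plus
conversations in which one was the topic).  All-zero weights (the cold
start) fall back to uniform choice.

Honest statements transmit the speaker's belief about the topic.
Dishonest ones start from the audience's estimated opinion — the
speaker's theory-of-mind entries for the recipients, mixed with the
partner weights and compressed with the configured method — and shift it
by `|2f−1|·Δ` upward for friends (`f > ½`) and for the speaker itself
(self-statements pretend `f = 1`), downward for enemies, not at all when
`f = ½` (white lie).  `Δ` solves `KL(shifted ‖ base) = κ_lie` by
bracketed root finding: the lie is made exactly as surprising as the
perceived climate says messages typically are.  For nearly degenerate
bases (`λ ≈ −1` with large `μ`) the KL grows so slowly in `Δ` that the
nominal solution is astronomical; the magnitude is capped at
`100·(μ+λ+2) + 100` pseudo-counts.  Lies blush with probability 0.1.

After sending, the speaker blends its theory of mind of each recipient
toward the payload, weighted by the credibility it predicts the
recipient will assign (the same judgment rule evaluated from the
speaker's own theory of mind and scales).

## Credibility judgment

A received message is judged before any state changes:

1. blush ⇒ credibility 0 (a certain lie);
2. a self-referential message strictly more negative than the receiver's
   current view of the speaker ⇒ credibility 1 (a confession: a liar
   would have embellished);
3. otherwise Bayes with the speaker's reputation `x̄` as prior and a
   surprise likelihood ratio:

       y = R·x̄ / (R·x̄ + 1 − x̄),
       ln R = ln(S/κ_h) + s·(1/S − 1/κ_h),
       S = max(κ_nh, κ_h + κ_lie),

   where `s = KL(payload ‖ receiver's belief about the topic)` is the
   observed surprise.  The honest hypothesis models the surprise as
   exponential with the adaptive climate scale `κ_h`; the dishonest
   hypothesis carries the honest baseline plus a climate-sized lie shift
   (`κ_h + κ_lie`, or the learned `κ_nh` when a toxic climate pushes it
   above that floor).  The floor matters: with equal scales `R ≡ 1`, and
   the whole system has an exact symmetric fixed point in which
   credibility never leaves the uniform prior 0.5 and no belief ever
   moves.  The cue-free credibility is clipped to `[1e−6, 1 − 1e−6]` so
   recorded surprises stay finite; cues override the clipping.

`κ_h` is a running *median* of the observed surprises (multiplicative
up/down tracker, step 1+α with α = 0.1, floor 1e−3): surprise
distributions in the simulation are heavy-tailed, and a mean-based scale
is inflated by rare huge disagreements until nothing looks suspicious,
producing a uniformly gullible population.  The estimate is deliberately
unconditional on the credibility judgment itself — conditioning it lets
early skepticism feed on itself until nothing looks credible.  `κ_nh`
tracks judged-dishonest surprises with responsibility weight `1−y`, and
`κ_lie` (the scale used to size one's own lies) follows `κ_h`.

## Knowledge updates

In fixed order after the judgment: the belief about the speaker becomes
the compressed mixture `y·(μ+1, λ) ⊕ (1−y)·(μ, λ+1)`; the theory of mind
about (speaker, topic) blends toward the payload with weight `y`
(DeGroot-style, no compression); the novelty filter clips the payload
against the same speaker's previous statement on the topic
(componentwise positive difference — repeating an opinion carries
nothing new); the belief about the topic becomes the compressed mixture
of accepting the novel increment (weight `y`) versus ignoring it.

Two bounded-memory elements keep the evidence flow on a sensible scale:

* **Per-statement evidence bound.**  The novelty increment applied to a
  topic belief is clipped to a total of 1 pseudo-count (direction
  preserved).  A message is a claim, not a data set: without the bound,
  a payload fattened by everything its speaker ever heard is absorbed
  wholesale, and opinions circulating along social loops (a→b→c→a)
  re-amplify exponentially — exponents reach 1e25 within 300 rounds and
  every mean freezes.
* **Belief capacity.**  Beliefs are clipped to 300 total pseudo-counts
  (mean preserved, concentration reduced), a finite evidence memory that
  keeps agents responsive late in a run.  300 counts correspond to a
  standard deviation of about 0.03 on a balanced opinion — roughly the
  resolution the task needs; an order of magnitude either way changes
  how stubborn late-run opinions are, not the qualitative dynamics.

Ledger updates close a reception: message counts per topic, conversation
counts per partner (answers belong to the conversation already counted;
a broadcast counts as a conversation with each recipient), and — for
self-referential messages — the friendship classification: a statement
about oneself is comparatively positive if its mean exceeds the running
mean of all statement means previously heard about oneself.

## Ensemble statistics

Reputation combines everyone's beliefs about an agent by summing
exponents: `(Σμ+1)/(Σμ+Σλ+2)`, the mean of the normalized product of
betas, cross-checked against the log-gamma beta-function ratio.
Contributors are clipped into the count domain `[0, ∞)` first, since
sums of compression-produced negative exponents can otherwise leave the
normalizable domain; uninformed contributors then drop out exactly.
Informedness is the centered dot product of an agent's belief means with
the true honesties; agreement the same between two agents' belief
vectors; neighborhood statistics weight neighbors (≥ 1 conversation) by
conversation counts.  The identity crossing of the ensemble-mean
reputation-vs-honesty curve is located by linear interpolation on the
honesty grid; if noise produces several sign changes, the median
crossing is reported.  Realized surprises (−ln of the probability
assigned to the true honesty status) are instrumentation only and are
collected without touching agent state; histograms put overflow —
including the infinite surprise of a maximally wrong certain judgment —
into the last bin.

## Reproducibility

Realization `k` of a run with base seed `σ` uses
`numpy.random.SeedSequence((σ, k))`; one generator per realization feeds
every draw in a fixed order, so event logs are byte-identical across
reruns and any single realization can be reproduced in isolation.  The
manifest (config, version, seeds) round-trips to an identical
configuration.

## Study conditions and scale

The headline conditions are 50 agents with honesties `i/49`, shyness and
friendship affinity uniform on `[0,1]` per realization, 300 rounds,
KL-optimal compression.  The package's reduced ensemble uses 20
realizations (the full 100 is a flag away); the compression-comparison
experiment uses the three-agent setup (honesties 0.1/0.5/0.9,
acquaintance tracking disabled so partner and topic choice are uniform)
with both compression methods on matched seeds.

## Known limitations

* The credibility machinery (the likelihood-ratio construction, the
  adaptive-scale estimator, the lie-magnitude rule, the novelty bound)
  is the model's open design space; the package's choices are documented
  above, and the emergent aggregate statistics are sensitive to them.
  In particular, the ensemble reputation curve tracks honesty closely
  (correlation > 0.99) and the border between net over- and
  underestimation is unstable between the low-30s and high-80s percent
  honesty across estimator variants — agents here are better judges
  than a strongly biased rumor mill would be.
* In the all-honest limit, beliefs rise well above the uniform prior but
  do not all converge beyond 0.9 within 300 rounds: every judgment mixes
  in `1−y` worth of "it was a lie" pseudo-counts, and with any bounded
  likelihood ratio `y` stays boundedly below 1, so reputations
  equilibrate below certainty.  Full convergence would require an
  unbounded trust channel that the cue set (blush/confession) does not
  provide in that limit.
* Group sizes measured as "partners with ≥ 100 conversations" come out
  around 42 of 49 possible, because a broadcast counts as a conversation
  with each recipient and broadcast sizes average ~20; counting only
  two-way conversations caps the statistic near 3 by arithmetic.  The
  statistic is reported as defined; its absolute level is a bookkeeping
  convention.
* Agents are all of the ordinary kind: no strategic speaker types, no
  predefined network graphs, no observables beyond honesty.
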