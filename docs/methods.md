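# Methods

## The game and its bookkeeping

A session is *n* participants (3 ≤ n ≤ a few dozen) playing *T* rounds
(default 60) of a donation game on a directed network that starts empty. A
link (i → j) means i pays `cost_c` per round to give j `benefit_b` per round
(defaults 1 and 2 tokens, so every link creates a net surplus of 1). Each
participant may add and/or remove up to `max_updates_per_round` (default 2)
of its own outgoing links per round; all decisions in a round are validated
against, and applied simultaneously to, the start-of-round network. Because
every actor controls only its own out-links, simultaneous updates cannot
conflict. Per-round payoff is `π = l·b − g·c` (l in-degree, g out-degree);
cumulative tokens are the endowment (default 1000) plus all round payoffs.
Replaying a session's event log from round 0 must reproduce every stored
round exactly; `Session.validate()` checks this along with degree, payoff
and token conservation, and `read_session` runs it on every file read.

The 30-second wall clock of live play is modelled as one discrete round;
there is no intra-round timing. Invalid updates (cap exceeded, duplicate
add, removing a non-recipient, self-link) are dropped with a logged
diagnostic by default — recorded data may contain artefacts — while the
simulator runs in strict mode, where any invalid update raises.

Behavioural type is `L = (g − l)/(g + l)`, undefined for isolated nodes and
excluded from averages; classification thresholds are ±1/3 (altruist above,
egoist below, fair in between — boundaries belong to fair).

## Visibility treatments

`visible_sets` is the single place treatment semantics live. In the
*recipient-only* treatment a focal participant sees its recipients and a
fresh uniform random sample of candidates (non-recipients; default sample
size 8 — the experimental interface's candidate count is not documented, so
this is a free configuration reported with results). In the *reciprocal*
treatment it additionally sees its providers, with nodes that are both
provider and recipient shown only as *reciprocals* (the four categories are
disjoint). Agent policies receive only this view, so recipient-only
decisions are structurally independent of provider identity.

## The synthetic agents

Human subjects leave outcome frequencies, not mechanisms. The agent policy
is the simplest stochastic rule family whose executed-event statistics can
be set directly to such frequencies:

1. **Activity.** Each update slot is used with probability `p_use_slot`
   (default 0.8); unused slots are the renounced updates visible in the
   activity accounting.
2. **Direction.** A used slot is an addition with probability
   `clip(p_add_given_both − add_density_slope · g/(n−1))`, falling back to
   the feasible action when only one is possible. The linear decrease in
   the agent's own normalized out-degree makes additions dominate on sparse
   networks and balances additions against removals at a stationary
   density slightly above `(p_add_given_both − ½)/add_density_slope`
   (slightly, because removal slots renounce somewhat more often). The
   preset slopes are calibrated to the stationary densities of the two
   treatments (0.95 → ≈0.62 recipient-only; 0.66 → ≈0.69 reciprocal).
3. **Target choice.** Additions draw a payoff side — strictly lower with
   probability `q_add_lower_payoff` — and pick uniformly within it.
   Removals draw a payoff side (`q_remove_higher_payoff`), then a
   generosity side within that payoff side (`q_remove_more_generous_reciprocal`
   for reciprocating recipients, the complement of
   `q_remove_less_generous` for the rest). In the reciprocal treatment an
   addition targets the provider pool with probability `q_secure_provider`,
   and the removal pool (reciprocator vs plain recipient) is chosen
   proportionally to pool size.

**Exactness of the coins.** A biased coin is only exercised when both of
its strict sides offer a target, and for removals the viability of *both*
payoff sides (a generosity choice or an equal-generosity target exists) is
established before any coin is drawn; otherwise the agent settles for an
equal-valued target (invisible to sign statistics) or renounces the slot.
Renouncement therefore never depends on a coin's outcome, and the sign
statistics of executed events are exactly Bernoulli(q) on each axis. This
is what makes the generator's parameters recoverable from the event
analysis within binomial error — the package's main calibration contract,
verified in the acceptance tests.

All comparisons use the previous round's displayed values (out-degree and
per-round payoff — accumulated tokens were never shown to subjects), held
fixed for both slots of a round.

**Two notions of neutrality.** Setting every q to ½ (`random_neutral`,
with a fair add/remove coin and zero slope) yields *sign-balanced* agents:
no marginal preference is detectable in the event analysis. This is not the
same as treating every possible link alike, because a donor's own link
raises its recipient's payoff by b and lowers its own by c: relative to a
focal participant, non-reciprocating recipients sit ≈ b + c tokens higher,
and providers sit lower. Target-uniform agents consequently *appear* to
prefer removing from the better-off (≈61% in simulation), and sign-balanced
agents under-add to providers per capita, which depresses bidirectionality
below the fixed-edge-count null. The package therefore ships both nulls:
`random_neutral` (sign-balanced, the behavioural null for preference
statistics) and `uniform_random` (target-uniform, the graph-level null that
matches the random-graph reciprocity model).

**Reproducibility.** One seed per session; the RNG stream is split per
(round, agent) by counter, so a session is byte-identical for a given
(config, params, seed) under any iteration order.

**What the generator does not emulate.** Agents are homogeneous and
memoryless: no learning, no per-participant heterogeneity, no reaction
times, no end-game effects. In particular the default presets do not
protect reciprocal links the way human subjects do, so their stationary
bidirectional fractions (≈0.56 recipient-only, ≈0.65 reciprocal) stay below
the values human sessions reach, and close to the matched random null.
Passing tests on synthetic sessions therefore validate the *pipeline*
(accounting, invariants, statistics, parameter recovery), not claims about
human behaviour.

## Network metrics

- **Generosity/density.** `g/(n−1)` — the fraction of *other* participants
  helped (using n would shift values by ~3% at these session sizes); the
  session series is the per-round mean over participants, 0 at round 0.
- **Stationarity.** A round is stationary when the absolute numerical
  derivative of the series is below 10% of the maximum absolute
  derivative. The derivative is `np.gradient`'s scheme — central
  differences with one-sided endpoints; a constant series is stationary
  everywhere. Stationary averages are the mean of the last 5 rounds (with a
  warning if that window leaves the detected stationary set).
- **Reciprocity.** The bidirectional fraction counts directed links whose
  reverse exists (`mode="dyads"` counts reciprocated dyads instead, for
  comparison). The null model fixes only the edge count: uniform random
  sets of m distinct ordered pairs, no self-loops, out-degrees free;
  expected fraction `(m−1)/(n(n−1)−1)` plus Monte Carlo percentiles. A
  degree-preserving null is deliberately not the default — the reference
  comparison is "same number of links".
- **Kendall τ.** τ-b (tie-corrected), because per-round count series are
  heavily tied; zero-variance participants are undefined and excluded from
  session means.
- **Pooling.** Treatment-level summaries average participant-level values
  within a session, then across sessions, so large sessions do not
  dominate.

## Event analysis

Each validated update is annotated with Δg and Δπ (target minus actor,
previous-round values) and a target category consistent with the
treatment's visibility. The first 10 rounds are excluded by default
(`min_round = 11`): the early network is too sparse for the comparisons to
mean much. Preference proportions are computed over strictly-signed events;
zero-delta events are excluded but counted and reported. The two-sided
exact binomial p-value against ½ is the doubled smaller tail capped at 1
(identical to the standard exact test at p = ½). Removal events split into
reciprocator/non-reciprocator by whether the target provided to the actor
in the preceding round; the split is refused (unless explicitly forced for
diagnostics) in the recipient-only treatment, where subjects could not see
it. Headline proportions pool raw events across sessions of a treatment;
per-session numbers are available from the same API. Per-participant
preference labels use a strict majority of nonzero-delta events; exact
halves and empty groups are `no_preference`.

## Numerical and design choices

- Integer token arithmetic throughout the domain layer; no floating-point
  accounting.
- Agent target picks sort candidate IDs before uniform selection so results
  are independent of set-iteration order.
- Uniform edge sampling in the null model encodes ordered pairs as integers
  with an O(1) reverse-index map; 10,000 replicates at (n=30, m=500) take a
  few seconds.
- Participant IDs are opaque (integers in the simulator, labels preserved
  by the dataset adapter); the per-viewer ID randomization of live
  experiments is out of scope — one canonical ID space.
- Problem sizes in the test suite: parameter recovery uses five sessions of
  n=30 × 60 rounds per parameter set (the neutral arm uses twenty, which
  tightens its 3-standard-error band to about ±2 percentage points);
  oracle checks enumerate exhaustively where feasible (all two-sided
  binomial p-values to n=25, all digraphs to n=4, m=4).

## Known limitations

- The deposited-data adapter reads a documented plain event-CSV layout; it
  has not been validated against the original archive's own format
  description, and refuses unrecognised layouts explicitly rather than
  guessing.
- Stationarity detection on a single noisy session can exclude occasional
  late rounds; the reference procedure was designed for session-averaged
  series.
- The agent policy family is deliberately minimal; matching human
  bidirectionality levels would need an explicit link-protection mechanism
  for reciprocals, which no current parameter encodes.
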