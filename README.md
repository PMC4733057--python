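# coopnet

Agent-based simulation and analysis of **donation-game dynamic social
networks** — settings in which a cooperative act (paying a cost *c* to give a
benefit *b* to someone else) is a directed link from donor to recipient that
keeps paying out every round until the donor cuts it. Participants cannot
control who gives to them; they only choose whom to give to, adjusting up to
two links per round. The package is for researchers in evolutionary game
theory and experimental economics who want to simulate such sessions, replay
recorded ones, and compute the standard statistics of the emerging networks.

## The model

Each of *n* participants starts with an endowment of 1000 tokens on an empty
network. In every round, a participant with *g* recipients (out-degree) and
*l* providers (in-degree) earns

```
π = l·b − g·c        (defaults b = 2, c = 1)
```

and may add or remove up to two of its outgoing links; all decisions are
applied simultaneously against the start-of-round network. The local
neighbourhood encodes the behavioural type

```
L = (g − l) / (g + l)  ∈ [−1, 1]
```

with altruists (L > 1/3), fair players (|L| ≤ 1/3) and egoists (L < −1/3).
Two information treatments are supported: **recipient-only** (providers are
invisible, so direct reciprocation is impossible) and **reciprocal**
(providers visible, nodes that both give and receive are grouped as
reciprocals).

The analysis layer computes, per session:

- mean normalized generosity *g/(n−1)* per round, its stationary regime
  (rounds where |numerical derivative| < 10% of the maximum) and last-5-round
  average;
- the bidirectional-link fraction with a fixed-edge-count random-graph null
  (closed form *(m−1)/(n(n−1)−1)* plus Monte Carlo band);
- behavioural-type series and classification;
- per-participant Kendall τ-b between the recipient and provider series;
- link-update event statistics: every add/remove annotated with
  Δg = g_target − g_actor and Δπ = π_target − π_actor from the previous
  (displayed) round, joint/marginal histograms, preference proportions with
  exact two-sided binomial tests against 0.5, reciprocator splits, quadrant
  fractions and per-participant preference labels.

The synthetic-agent policy realises the behavioural patterns such
experiments report — payoff-inequity aversion (add to the worse-off, remove
from the better-off) with secondary generosity effects — through per-axis
biased coins whose parameters are exactly recoverable from the event
analysis (see `docs/methods.md`).

## Worked example

`examples/01_round_mechanics.py` replays the canonical first round: a focal
participant adds two links while four others add links to the focal.

```
focal: g=2 recipients, l=4 providers
round payoff = l*b - g*c = 4*2 - 2*1 = 6
tokens at start of round 2: 1006
```

The focal pays 2 tokens for its two donations, receives 8 from its four
providers, and climbs from 1000 to 1006 tokens.

`examples/03_event_analysis.py` simulates three reciprocal-treatment
sessions (n = 30, 60 rounds) and prints, for rounds 11–60:

```
additions   : 58.96% to lower-payoff targets (p=5.3e-11)
removals    : 62.71% from higher-payoff targets (p=2e-06)
reciprocators    : 77.38% of removals hit more generous targets (n=444)
non-reciprocators: 72.41% of removals hit less generous targets (n=109)
```

i.e. links flow toward the worse-off and are cut toward the better-off
(payoff-inequity aversion), while generosity matters in opposite directions
for reciprocating and non-reciprocating recipients. The remaining examples
cover network metrics, the reciprocity null model, and session files.

## Command line

A thin CLI wraps the library:

```
coopnet simulate --preset reciprocal_default --n 30 --rounds 60 --seed 7 -o s.json
coopnet analyze s.json
coopnet events s.json --event-log events.csv
coopnet null --n 30 --m 500
coopnet report -o report.json
```

Session files are self-describing JSON (config, per-round edge lists, event
log); reading one replays its event log under strict validation, so a file
that loads is internally consistent. `coopnet.io.read_deposited_dataset`
adapts directories of per-session event CSVs (sub-files B–J, columns
`round,actor,target,action`) into the same representation.

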