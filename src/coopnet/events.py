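"""Link-update event statistics.

Every validated link update is annotated with the generosity and payoff
differences between target (model) and actor (focal), computed from the
displayed — i.e. previous round's — state: ``delta_g = g_target - g_actor``
and ``delta_pi = pi_target - pi_actor`` where ``pi`` is the *per-round*
payoff ``l*b - g*c`` (accumulated tokens were never shown to subjects).

From the annotated events the module builds the joint histogram
``p(delta_g, delta_pi)`` with its marginals, tests preference proportions
(e.g. the fraction of additions toward strictly less successful targets)
against the 50% null with an exact two-sided binomial test, splits removals
by whether the target was reciprocating, and labels per-participant
preferences by strict majority.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core import Action, DomainError, Session, Treatment

#: First analysed round; the initial rounds are dominated by the empty
#: network (no providers or recipients exist yet) and are excluded.
DEFAULT_MIN_ROUND = 11


@dataclass(frozen=True)
class LinkEventRecord:
    """One annotated add/remove decision.

    ``target_category`` reflects what the actor's interface showed in the
    preceding round: ``candidate`` or (reciprocal treatment) ``provider``
    for additions, ``recipient`` or ``reciprocal`` for removals.
    """

    round: int
    actor: object
    target: object
    action: Action
    target_category: str
    delta_g: int
    delta_pi: int
    treatment: Treatment


def annotate_events(session: Session) -> list[LinkEventRecord]:
    """Annotate every validated update with deltas and target category."""
    treatment = session.config.treatment
    known = set(session.participants)
    records: list[LinkEventRecord] = []
    for ev in session.events:
        if ev.actor not in known or ev.target not in known:
            raise DomainError(f"event references unknown participant: {ev}")
        prev = session.rounds[ev.round - 1]
        reverse = (ev.target, ev.actor) in prev.edges
        if ev.action is Action.ADD:
            category = ("provider"
                        if treatment is Treatment.RECIPROCAL and reverse else "candidate")
        else:
            category = ("reciprocal"
                        if treatment is Treatment.RECIPROCAL and reverse else "recipient")
        records.append(LinkEventRecord(
            round=ev.round, actor=ev.actor, target=ev.target, action=ev.action,
            target_category=category,
            delta_g=prev.g[ev.target] - prev.g[ev.actor],
            delta_pi=prev.round_payoff[ev.target] - prev.round_payoff[ev.actor],
            treatment=treatment,
        ))
    return records


def filter_rounds(events: Iterable[LinkEventRecord],
                  min_round: int = DEFAULT_MIN_ROUND) -> list[LinkEventRecord]:
    """Keep only events from ``min_round`` onward (the analysed regime)."""
    return [e for e in events if e.round >= min_round]


@dataclass(frozen=True)
class EventHistogram:
    """Joint counts over integer (delta_g, delta_pi) cells with marginals and means."""

    joint: Mapping[tuple[int, int], int]
    marginal_g: Mapping[int, int]
    marginal_pi: Mapping[int, int]
    mean_delta_g: float
    mean_delta_pi: float
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (delta_g, delta_pi, count)."""
        rows = [(dg, dpi, c) for (dg, dpi), c in sorted(self.joint.items())]
        return pd.DataFrame(rows, columns=["delta_g", "delta_pi", "count"])


def build_histogram(events: Sequence[LinkEventRecord]) -> EventHistogram:
    """Joint histogram ``p(delta_g, delta_pi)`` and its two marginals."""
    if not events:
        raise DomainError("cannot build a histogram from zero events")
    joint = Counter((e.delta_g, e.delta_pi) for e in events)
    marginal_g = Counter(e.delta_g for e in events)
    marginal_pi = Counter(e.delta_pi for e in events)
    return EventHistogram(
        joint=dict(joint), marginal_g=dict(marginal_g), marginal_pi=dict(marginal_pi),
        mean_delta_g=float(np.mean([e.delta_g for e in events])),
        mean_delta_pi=float(np.mean([e.delta_pi for e in events])),
        n_events=len(events),
    )


def exact_binomial_p(k: int, n: int) -> float:
    """Exact two-sided binomial p-value against p=1/2.

    Defined as the doubled smaller tail, capped at 1:
    ``min(1, 2 * min(P(X <= k), P(X >= k)))`` with X ~ Binomial(n, 1/2).
    """
    if n < 1 or not 0 <= k <= n:
        raise DomainError(f"invalid binomial test arguments k={k}, n={n}")
    lower = scipy.stats.binom.cdf(k, n, 0.5)
    upper = scipy.stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class PreferenceTest:
    """Preference proportion on one delta axis with its exact binomial test.

    ``proportion`` is the share of strictly-negative-delta events among all
    nonzero-delta events; zero-delta events are excluded (too few to support
    analysis) but counted in ``n_zero``.
    """

    n_minus: int
    n_plus: int
    n_zero: int
    proportion: float
    p_value: float


def preference_proportion(marginal: Mapping[int, int]) -> PreferenceTest:
    """Test whether negative and positive deltas are equally frequent."""
    n_minus = sum(c for d, c in marginal.items() if d < 0)
    n_plus = sum(c for d, c in marginal.items() if d > 0)
    n_zero = sum(c for d, c in marginal.items() if d == 0)
    if n_minus + n_plus < 1:
        raise DomainError("all deltas are zero; preference proportion undefined")
    return PreferenceTest(
        n_minus=n_minus, n_plus=n_plus, n_zero=n_zero,
        proportion=n_minus / (n_minus + n_plus),
        p_value=exact_binomial_p(n_minus, n_minus + n_plus),
    )


def _maybe_preference(marginal: Mapping[int, int]) -> PreferenceTest | None:
    """`preference_proportion`, but ``None`` when every delta is zero."""
    try:
        return preference_proportion(marginal)
    except DomainError:
        return None


def split_by_reciprocation(events: Iterable[LinkEventRecord], session: Session,
                           allow_recipient_only: bool = False) -> dict:
    """Partition removal events by whether the target was reciprocating.

    A removal is a *reciprocator* event iff the target also provided to the
    actor in the preceding round.  In the recipient-only treatment the split
    was invisible to subjects, so calling this there is an error unless
    explicitly requested for diagnostics.
    """
    if (session.config.treatment is Treatment.RECIPIENT_ONLY
            and not allow_recipient_only):
        raise DomainError(
            "reciprocation split is unobservable in the recipient-only treatment; "
            "pass allow_recipient_only=True for diagnostics")
    recip, non_recip = [], []
    for e in events:
        if e.action is not Action.REMOVE:
            continue
        prev = session.rounds[e.round - 1]
        (recip if (e.target, e.actor) in prev.edges else non_recip).append(e)
    return {"reciprocator": recip, "non_reciprocator": non_recip}


@dataclass(frozen=True)
class QuadrantFractions:
    """Fractions of events in the four (sign delta_g, sign delta_pi) quadrants.

    Fractions are over events with *both* deltas nonzero and sum to 1;
    events on either axis are excluded and reported as zero-counts.
    """

    fractions: Mapping[tuple[int, int], float]
    n_nonzero: int
    n_zero_g: int
    n_zero_pi: int
    n_zero_both: int


def quadrant_fractions(events: Sequence[LinkEventRecord]) -> QuadrantFractions:
    if not events:
        raise DomainError("no events")
    counts = Counter()
    zg = zpi = zboth = 0
    for e in events:
        sg, spi = int(np.sign(e.delta_g)), int(np.sign(e.delta_pi))
        if sg == 0 and spi == 0:
            zboth += 1
        elif sg == 0:
            zg += 1
        elif spi == 0:
            zpi += 1
        else:
            counts[(sg, spi)] += 1
    n = sum(counts.values())
    fractions = {q: (counts.get(q, 0) / n if n else 0.0)
                 for q in ((1, 1), (1, -1), (-1, 1), (-1, -1))}
    return QuadrantFractions(fractions=fractions, n_nonzero=n,
                             n_zero_g=zg, n_zero_pi=zpi, n_zero_both=zboth)


PREFERS_MORE = "prefers_more"
PREFERS_LESS = "prefers_less"
NO_PREFERENCE = "no_preference"


def per_participant_preference(events: Iterable[LinkEventRecord]) -> dict:
    """Label each actor's preference per (action, axis) by strict majority.

    A participant *prefers more* (generous/successful) targets on an axis if
    strictly more than half of its nonzero-delta events have positive delta;
    exact half, or no nonzero-delta events, yields ``no_preference``.
    """
    grouped: dict = {}
    for e in events:
        for axis, delta in (("generosity", e.delta_g), ("payoff", e.delta_pi)):
            if delta == 0:
                continue
            key = (e.actor, e.action.value, axis)
            pos, tot = grouped.get(key, (0, 0))
            grouped[key] = (pos + (delta > 0), tot + 1)
    labels: dict = {}
    for (actor, action, axis), (pos, tot) in grouped.items():
        if 2 * pos > tot:
            label = PREFERS_MORE
        elif 2 * pos < tot:
            label = PREFERS_LESS
        else:
            label = NO_PREFERENCE
        labels.setdefault(actor, {})[(action, axis)] = label
    return labels


def update_activity_series(session: Session) -> pd.DataFrame:
    """Per-round counts of additions, removals and renounced update slots.

    Each round offers ``max_updates_per_round * n`` slots in total, so
    ``adds + removes + renounced`` equals that constant in every round.
    """
    cap = session.config.max_updates_per_round * len(session.participants)
    rows = []
    for t in range(1, session.n_rounds_played + 1):
        evs = session.events_in_round(t)
        adds = sum(1 for e in evs if e.action is Action.ADD)
        removes = sum(1 for e in evs if e.action is Action.REMOVE)
        rows.append({"round": t, "adds": adds, "removes": removes,
                     "renounced": cap - adds - removes})
    return pd.DataFrame(rows)


def event_report(sessions: Sequence[Session], min_round: int = DEFAULT_MIN_ROUND) -> dict:
    """Headline event-analysis proportions, pooling raw events across
    sessions of a single treatment.

    Returns, per action, the marginal preference tests on both axes (for
    additions the payoff proportion reported is the *lower-payoff* share;
    for removals the *higher-payoff* and, per sub-pool, the generosity
    shares), plus quadrant fractions for reciprocator removals.
    """
    treatments = {s.config.treatment for s in sessions}
    if len(treatments) != 1:
        raise DomainError("event_report pools sessions of a single treatment")
    treatment = treatments.pop()
    events: list[LinkEventRecord] = []
    for s in sessions:
        events.extend(filter_rounds(annotate_events(s), min_round))
    adds = [e for e in events if e.action is Action.ADD]
    removes = [e for e in events if e.action is Action.REMOVE]
    out: dict = {"treatment": treatment.value, "n_events": len(events),
                 "min_round": min_round}
    if adds:
        h = build_histogram(adds)
        pi_test = _maybe_preference(h.marginal_pi)
        g_test = _maybe_preference(h.marginal_g)
        out["add"] = {
            "n": len(adds),
            "frac_lower_payoff": pi_test and pi_test.proportion,
            "p_payoff": pi_test and pi_test.p_value,
            "frac_less_generous": g_test and g_test.proportion,
            "p_generosity": g_test and g_test.p_value,
            "mean": (h.mean_delta_g, h.mean_delta_pi),
        }
    if removes:
        h = build_histogram(removes)
        pi_test = _maybe_preference(h.marginal_pi)
        g_test = _maybe_preference(h.marginal_g)
        out["remove"] = {
            "n": len(removes),
            "frac_higher_payoff": pi_test and 1.0 - pi_test.proportion,
            "p_payoff": pi_test and pi_test.p_value,
            "frac_less_generous": g_test and g_test.proportion,
            "p_generosity": g_test and g_test.p_value,
            "mean": (h.mean_delta_g, h.mean_delta_pi),
        }
        if treatment is Treatment.RECIPROCAL:
            recip_evs, plain_evs = [], []
            for s in sessions:
                evs = filter_rounds(annotate_events(s), min_round)
                split = split_by_reciprocation(evs, s)
                recip_evs.extend(split["reciprocator"])
                plain_evs.extend(split["non_reciprocator"])
            sub = {}
            if recip_evs:
                hr = build_histogram(recip_evs)
                t = _maybe_preference(hr.marginal_g)
                q = quadrant_fractions(recip_evs)
                sub["reciprocator"] = {
                    "n": len(recip_evs),
                    "frac_more_generous": t and 1.0 - t.proportion,
                    "p": t and t.p_value,
                    "frac_more_generous_and_successful": q.fractions[(1, 1)],
                    "mean": (hr.mean_delta_g, hr.mean_delta_pi),
                }
            if plain_evs:
                hp = build_histogram(plain_evs)
                t = _maybe_preference(hp.marginal_g)
                sub["non_reciprocator"] = {
                    "n": len(plain_evs),
                    "frac_less_generous": t and t.proportion,
                    "p": t and t.p_value,
                    "mean": (hp.mean_delta_g, hp.mean_delta_pi),
                }
            out["remove_by_reciprocation"] = sub
    return out
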