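"""Domain types and round mechanics of the directed-link donation game.

A cooperative act — paying a cost ``c`` to provide a benefit ``b`` to another
participant — is a directed link from donor to recipient that persists, and
pays out, every round until the donor removes it.  A participant's *generosity*
``g`` is their out-degree (number of recipients), ``l`` their in-degree
(number of providers), and the per-round payoff is ``l*b - g*c``.  The
behavioural type ``L = (g - l) / (g + l)`` summarises whether a node gives
more than it receives (altruist), the reverse (egoist), or roughly balances
the two (fair player).

This module is a pure domain layer: immutable session/round types, the
simultaneous round-update rule, and payoff/token accounting.  Serialization
lives in :mod:`coopnet.io`, agent behaviour in :mod:`coopnet.simulate`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

ParticipantID = Hashable

ALTRUIST = "altruist"
FAIR = "fair"
EGOIST = "egoist"

#: Classification threshold on L: altruist above +1/3, egoist below -1/3.
TYPE_THRESHOLD = 1.0 / 3.0


class Treatment(str, enum.Enum):
    """Information condition of a session.

    In the recipient-only treatment participants see their recipients and a
    random candidate sample but never their providers, so intentional direct
    reciprocation is impossible.  In the reciprocal treatment providers are
    visible too, and nodes that are simultaneously provider and recipient are
    grouped as reciprocals.
    """

    RECIPIENT_ONLY = "recipient_only"
    RECIPROCAL = "reciprocal"


class DomainError(ValueError):
    """A call violated a documented precondition of the domain layer."""


class InvalidUpdateError(DomainError):
    """A link update failed validation while strict mode was active."""


class Action(str, enum.Enum):
    ADD = "add"
    REMOVE = "remove"


@dataclass(frozen=True)
class SessionConfig:
    """Immutable parameters of one experimental session.

    Defaults follow the behavioural experiment this package models: benefit
    2 tokens, cost 1 token per link per round, a 1000-token endowment, 60
    rounds, and up to two link updates per participant per round.
    """

    n_participants: int
    n_rounds: int = 60
    benefit_b: int = 2
    cost_c: int = 1
    endowment: int = 1000
    max_updates_per_round: int = 2
    treatment: Treatment = Treatment.RECIPIENT_ONLY
    candidate_sample_size: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        if self.n_participants < 3:
            raise DomainError("n_participants must be >= 3")
        if self.n_rounds < 1:
            raise DomainError("n_rounds must be >= 1")
        if not (self.benefit_b > self.cost_c > 0):
            raise DomainError("requires benefit_b > cost_c > 0")
        if self.max_updates_per_round < 1:
            raise DomainError("max_updates_per_round must be >= 1")
        if self.candidate_sample_size < 1:
            raise DomainError("candidate_sample_size must be >= 1")

    @property
    def participants(self) -> tuple[int, ...]:
        """Canonical 0-based participant IDs."""
        return tuple(range(self.n_participants))


def round_payoff(g: int, l: int, b: int, c: int) -> int:
    """Per-round payoff ``l*b - g*c`` of a node with g recipients, l providers.

    May be negative for nodes that give much more than they receive.
    """
    if g < 0 or l < 0:
        raise DomainError(f"degree counts must be non-negative, got g={g}, l={l}")
    if b <= 0 or c <= 0:
        raise DomainError("benefit and cost must be positive")
    return l * b - g * c


def accumulate_tokens(endowment: int, round_payoffs: Iterable[int]) -> int:
    """Tokens held after adding every round's payoff to the endowment."""
    return endowment + sum(round_payoffs)


def behavioural_type(g: int, l: int) -> float | None:
    """Behavioural type ``L = (g - l) / (g + l)`` in [-1, 1].

    Returns ``None`` for isolated nodes (g = l = 0), a legitimate *undefined*
    value that callers must exclude from averages.
    """
    if g < 0 or l < 0:
        raise DomainError(f"degree counts must be non-negative, got g={g}, l={l}")
    if g + l == 0:
        return None
    return (g - l) / (g + l)


def classify_type(L: float) -> str:
    """Map a behavioural type to altruist (L > 1/3), fair (|L| <= 1/3) or egoist."""
    if not -1.0 <= L <= 1.0:
        raise DomainError(f"L must lie in [-1, 1], got {L}")
    if L > TYPE_THRESHOLD:
        return ALTRUIST
    if L < -TYPE_THRESHOLD:
        return EGOIST
    return FAIR


@dataclass(frozen=True)
class LinkUpdate:
    """One add/remove decision by ``actor`` about its out-link to ``target``."""

    actor: ParticipantID
    target: ParticipantID
    action: Action

    def __post_init__(self) -> None:
        object.__setattr__(self, "action", Action(self.action))
        if self.actor == self.target:
            raise DomainError(f"self-link update by {self.actor!r}")


@dataclass(frozen=True)
class LoggedUpdate:
    """A validated link update stamped with the round in which it took effect."""

    round: int
    actor: ParticipantID
    target: ParticipantID
    action: Action

    def __post_init__(self) -> None:
        object.__setattr__(self, "action", Action(self.action))


@dataclass(frozen=True)
class RoundState:
    """The donation network and per-participant bookkeeping after one round.

    ``g``/``l`` are out-/in-degrees, ``round_payoff`` the tokens earned this
    round and ``cumulative_tokens`` the endowment plus all payoffs so far.
    """

    round_index: int
    participants: tuple[ParticipantID, ...]
    edges: frozenset[tuple[ParticipantID, ParticipantID]]
    g: Mapping[ParticipantID, int]
    l: Mapping[ParticipantID, int]
    round_payoff: Mapping[ParticipantID, int]
    cumulative_tokens: Mapping[ParticipantID, int]

    @classmethod
    def initial(cls, config: SessionConfig,
                participants: Sequence[ParticipantID] | None = None) -> "RoundState":
        """Round 0: disconnected nodes, zero payoffs, full endowment."""
        ids = tuple(participants) if participants is not None else config.participants
        zeros = {p: 0 for p in ids}
        return cls(
            round_index=0,
            participants=ids,
            edges=frozenset(),
            g=dict(zeros),
            l=dict(zeros),
            round_payoff=dict(zeros),
            cumulative_tokens={p: config.endowment for p in ids},
        )

    @classmethod
    def from_edges(cls, round_index: int,
                   edges: Iterable[tuple[ParticipantID, ParticipantID]],
                   previous: "RoundState", config: SessionConfig) -> "RoundState":
        """Build the state that follows ``previous`` once ``edges`` is the network."""
        ids = previous.participants
        known = set(ids)
        edge_set = frozenset((d, r) for d, r in edges)
        for d, r in edge_set:
            if d == r:
                raise DomainError(f"self-edge {d!r} in round {round_index}")
            if d not in known or r not in known:
                raise DomainError(f"edge ({d!r}, {r!r}) references unknown participant")
        g = {p: 0 for p in ids}
        l = {p: 0 for p in ids}
        for d, r in edge_set:
            g[d] += 1
            l[r] += 1
        payoff = {p: round_payoff(g[p], l[p], config.benefit_b, config.cost_c) for p in ids}
        tokens = {p: previous.cumulative_tokens[p] + payoff[p] for p in ids}
        return cls(round_index=round_index, participants=ids, edges=edge_set,
                   g=g, l=l, round_payoff=payoff, cumulative_tokens=tokens)

    def recipients_of(self, focal: ParticipantID) -> frozenset[ParticipantID]:
        return frozenset(r for d, r in self.edges if d == focal)

    def providers_of(self, focal: ParticipantID) -> frozenset[ParticipantID]:
        return frozenset(d for d, r in self.edges if r == focal)

    def check_invariants(self, config: SessionConfig) -> None:
        """Degree/payoff conservation; raises DomainError on violation."""
        m = len(self.edges)
        if sum(self.g.values()) != m or sum(self.l.values()) != m:
            raise DomainError(f"round {self.round_index}: degree sums != edge count")
        total = sum(self.round_payoff.values())
        expected = m * (config.benefit_b - config.cost_c)
        if total != expected:
            raise DomainError(
                f"round {self.round_index}: payoff sum {total} != |E|*(b-c) = {expected}")
        for p in self.participants:
            want = round_payoff(self.g[p], self.l[p], config.benefit_b, config.cost_c)
            if self.round_payoff[p] != want:
                raise DomainError(f"round {self.round_index}: payoff of {p!r} inconsistent")


@dataclass(frozen=True)
class VisibleSets:
    """What the interface shows a focal participant before it decides.

    ``providers``/``reciprocals`` are ``None`` in the recipient-only
    treatment: the information does not exist for the subject, and agent
    policies therefore cannot depend on it.  In the reciprocal treatment the
    four categories are disjoint — nodes that are both provider and recipient
    appear only under ``reciprocals``.
    """

    recipients: frozenset[ParticipantID]
    candidates: frozenset[ParticipantID]
    providers: frozenset[ParticipantID] | None = None
    reciprocals: frozenset[ParticipantID] | None = None


def visible_sets(state: RoundState, focal: ParticipantID, treatment: Treatment,
                 candidate_sample: Iterable[ParticipantID]) -> VisibleSets:
    """Partition the focal participant's screen into disjoint target categories."""
    treatment = Treatment(treatment)
    recipients = state.recipients_of(focal)
    candidates = frozenset(candidate_sample)
    overlap = candidates & (recipients | {focal})
    if overlap:
        logger.warning("candidate sample for %r overlapped %r; filtered", focal, overlap)
        candidates -= overlap
    if treatment is Treatment.RECIPIENT_ONLY:
        return VisibleSets(recipients=recipients, candidates=candidates)
    providers = state.providers_of(focal)
    reciprocals = recipients & providers
    return VisibleSets(
        recipients=recipients - reciprocals,
        candidates=candidates - providers,
        providers=providers - reciprocals,
        reciprocals=reciprocals,
    )


@dataclass(frozen=True)
class RoundResult:
    """Outcome of applying one round of updates: the next state, the updates
    that passed validation (in application order) and the rejected ones with
    a human-readable reason each."""

    state: RoundState
    applied: tuple[LinkUpdate, ...]
    rejected: tuple[tuple[LinkUpdate, str], ...]


def validate_and_apply_round(
    state: RoundState,
    updates: Mapping[ParticipantID, Sequence[LinkUpdate]],
    config: SessionConfig,
    strict: bool = False,
) -> RoundResult:
    """Apply all participants' decisions simultaneously against the start-of-round state.

    Every update is validated against ``state`` (the network everyone saw
    while deciding), never against other updates of the same round; because
    each actor controls only its own out-links, concurrent decisions cannot
    conflict.  Per actor, at most ``config.max_updates_per_round`` updates are
    accepted and duplicates within the round are rejected.  Invalid updates
    are dropped with a logged diagnostic, or raise
    :class:`InvalidUpdateError` when ``strict`` is true.
    """
    known = set(state.participants)
    applied: list[LinkUpdate] = []
    rejected: list[tuple[LinkUpdate, str]] = []

    def reject(up: LinkUpdate, reason: str) -> None:
        if strict:
            raise InvalidUpdateError(
                f"round {state.round_index + 1}, actor {up.actor!r}: {reason}")
        logger.warning("round %d, actor %r: dropped update %r (%s)",
                       state.round_index + 1, up.actor, up, reason)
        rejected.append((up, reason))

    for actor, ups in updates.items():
        if actor not in known:
            for up in ups:
                reject(up, "unknown actor")
            continue
        recipients = state.recipients_of(actor)
        accepted_here: list[LinkUpdate] = []
        touched: set[tuple[ParticipantID, Action]] = set()
        for up in ups:
            if up.actor != actor:
                reject(up, "update filed under a different actor")
                continue
            if len(accepted_here) >= config.max_updates_per_round:
                reject(up, f"exceeds cap of {config.max_updates_per_round} updates")
                continue
            if up.target not in known:
                reject(up, "unknown target")
                continue
            if (up.target, up.action) in touched:
                reject(up, "duplicate update this round")
                continue
            if up.action is Action.ADD and up.target in recipients:
                reject(up, "add targets an existing recipient")
                continue
            if up.action is Action.ADD and any(
                    a.target == up.target and a.action is Action.ADD for a in accepted_here):
                reject(up, "duplicate add this round")
                continue
            if up.action is Action.REMOVE and up.target not in recipients:
                reject(up, "remove targets a non-recipient")
                continue
            touched.add((up.target, up.action))
            accepted_here.append(up)
        applied.extend(accepted_here)

    edges = set(state.edges)
    for up in applied:
        if up.action is Action.ADD:
            edges.add((up.actor, up.target))
        else:
            edges.discard((up.actor, up.target))
    next_state = RoundState.from_edges(state.round_index + 1, edges, state, config)
    return RoundResult(state=next_state, applied=tuple(applied), rejected=tuple(rejected))


@dataclass
class Session:
    """One complete session: config, ordered round states, validated event log.

    ``rounds[0]`` is the empty initial network; ``rounds[t]`` is the network
    at the end of round ``t``.  ``events`` holds every validated link update
    in application order.  ``metadata`` carries provenance (seed, generator,
    labels) and is never interpreted by analyses.
    """

    config: SessionConfig
    rounds: list[RoundState]
    events: list[LoggedUpdate]
    metadata: dict = field(default_factory=dict)

    @property
    def participants(self) -> tuple[ParticipantID, ...]:
        return self.rounds[0].participants

    @property
    def n_rounds_played(self) -> int:
        return len(self.rounds) - 1

    def events_in_round(self, round_index: int) -> list[LoggedUpdate]:
        return [e for e in self.events if e.round == round_index]

    def validate(self) -> None:
        """Check every stored invariant, including full event-log replay.

        Raises :class:`DomainError` naming the first offending round.
        """
        if not self.rounds:
            raise DomainError("session has no rounds")
        if self.rounds[0].edges:
            raise DomainError("round 0 must be an empty network")
        for state in self.rounds:
            state.check_invariants(self.config)
        for t, state in enumerate(self.rounds):
            for p in self.participants:
                expect = accumulate_tokens(
                    self.config.endowment,
                    (self.rounds[s].round_payoff[p] for s in range(t + 1)))
                if state.cumulative_tokens[p] != expect:
                    raise DomainError(f"round {t}: token audit failed for {p!r}")
        replayed = replay(self.config, self.participants, self.events,
                          n_rounds=self.n_rounds_played)
        for t, state in enumerate(self.rounds):
            if replayed[t].edges != state.edges:
                raise DomainError(f"round {t}: replayed edge set differs from stored state")


def replay(config: SessionConfig, participants: Sequence[ParticipantID],
           events: Iterable[LoggedUpdate], n_rounds: int) -> list[RoundState]:
    """Rebuild all round states from round 0 by re-applying the event log.

    Events are grouped by round and validated strictly; the result is the
    authoritative state sequence for a well-formed log.
    """
    by_round: dict[int, dict[ParticipantID, list[LinkUpdate]]] = {}
    for ev in events:
        if ev.round < 1 or ev.round > n_rounds:
            raise DomainError(f"event in round {ev.round} outside 1..{n_rounds}")
        by_round.setdefault(ev.round, {}).setdefault(ev.actor, []).append(
            LinkUpdate(actor=ev.actor, target=ev.target, action=ev.action))
    states = [RoundState.initial(config, participants)]
    for t in range(1, n_rounds + 1):
        result = validate_and_apply_round(states[-1], by_round.get(t, {}), config, strict=True)
        states.append(result.state)
    return states
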