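"""Agent-based generator of synthetic donation-game sessions.

Human subjects in this game leave only outcome statistics behind — the
fractions of links added to less successful targets, removed from more
successful or less generous ones, and so on.  The agents here realise those
statistics with the simplest two-stage stochastic policy that can be tuned to
the observed proportions:

1. *activity*: each of the (up to two) update slots is used with probability
   ``p_use_slot``, otherwise renounced;
2. *direction*: a used slot becomes an addition or a removal; the addition
   probability decreases linearly with the agent's current normalized
   generosity, so early rounds are dominated by additions and the network
   settles where additions and removals balance;
3. *target choice*: additions are biased toward lower-payoff targets
   (payoff-inequity aversion), removals toward higher-payoff targets, with a
   secondary generosity bias whose direction differs between reciprocating
   and non-reciprocating recipients.

All payoff/generosity comparisons use the *previous round's* displayed
values, exactly what the experimental interface showed.  Sessions are fully
reproducible from ``(config, params, seed)``: one seed sequence per session,
split per (round, agent) by counter, so the result does not depend on
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    Action,
    DomainError,
    LinkUpdate,
    LoggedUpdate,
    RoundState,
    Session,
    SessionConfig,
    Treatment,
    validate_and_apply_round,
    visible_sets,
    VisibleSets,
)


@dataclass(frozen=True)
class BehaviourParams:
    """Decision-rule parameters of the synthetic agents.

    Parameters
    ----------
    p_use_slot:
        Probability that each update slot is used in a round; the complement
        produces renounced updates.
    p_add_given_both, add_density_slope:
        When both adding and removing are feasible, the slot is an addition
        with probability ``clip(p_add_given_both - add_density_slope * g/(n-1))``.
        The linear decrease in the agent's own normalized generosity makes
        additions dominate while the network is sparse and balances
        additions against removals at a density a little above
        ``(p_add_given_both - 1/2) / add_density_slope`` (removal slots are
        renounced somewhat more often than addition slots, which shifts the
        balance point upward; the preset slopes are calibrated empirically
        to each treatment's stationary density).
    q_add_lower_payoff:
        Probability an addition targets a strictly lower-payoff node (else a
        strictly higher one; ties are used only as fallback).
    q_remove_higher_payoff:
        Probability a removal targets a strictly higher-payoff recipient.
    q_remove_less_generous:
        Probability a removal targets a strictly less generous recipient,
        applied to non-reciprocating recipients (and to all recipients in the
        recipient-only treatment, where reciprocation is invisible).
    q_remove_more_generous_reciprocal:
        Analogous generosity bias for reciprocating recipients, but pointing
        at *more* generous targets (reciprocal treatment only).
    q_secure_provider:
        Probability an addition goes to a visible provider rather than a
        candidate (reciprocal treatment only) — securing a benefactor versus
        increasing exposure.
    uniform_targets:
        When true, every q is ignored and targets are drawn uniformly from
        the full visible pool.  This is a *graph-level* null (each possible
        link is treated alike) as opposed to the *sign-balanced* null of
        setting every q to 1/2: because a donor's own link raises the
        recipient's payoff and lowers its own, the two notions of
        neutrality differ in this game.
    """

    p_use_slot: float = 0.8
    p_add_given_both: float = 1.0
    add_density_slope: float = 0.8
    q_add_lower_payoff: float = 0.60
    q_remove_higher_payoff: float = 0.67
    q_remove_less_generous: float = 0.56
    q_remove_more_generous_reciprocal: float = 0.73
    q_secure_provider: float = 0.45
    uniform_targets: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.type == "bool" or f.name == "add_density_slope":
                continue
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{f.name} must lie in [0, 1], got {v}")
        if self.add_density_slope < 0:
            raise DomainError("add_density_slope must be non-negative")


#: Named parameter presets.  The two defaults are calibrated to the observed
#: event proportions of each treatment; ``random_neutral`` is an unbiased
#: agent (all target choices uniform) used as a behavioural null.
PRESETS: dict[str, BehaviourParams] = {
    "recipient_only_default": BehaviourParams(
        p_use_slot=0.8,
        p_add_given_both=1.0,
        add_density_slope=0.95,
        q_add_lower_payoff=0.60,
        q_remove_higher_payoff=0.67,
        q_remove_less_generous=0.56,
        q_remove_more_generous_reciprocal=0.5,
        q_secure_provider=0.0,
    ),
    "reciprocal_default": BehaviourParams(
        p_use_slot=0.8,
        p_add_given_both=1.0,
        add_density_slope=0.66,
        q_add_lower_payoff=0.61,
        q_remove_higher_payoff=0.59,
        q_remove_less_generous=0.71,
        q_remove_more_generous_reciprocal=0.73,
        q_secure_provider=0.45,
    ),
    # fully exchangeable null: fair coin between add and remove, uniform
    # targets, no coupling between an agent's state and its decisions
    "random_neutral": BehaviourParams(
        p_use_slot=0.8,
        p_add_given_both=0.5,
        add_density_slope=0.0,
        q_add_lower_payoff=0.5,
        q_remove_higher_payoff=0.5,
        q_remove_less_generous=0.5,
        q_remove_more_generous_reciprocal=0.5,
        q_secure_provider=0.0,
    ),
    # graph-level null for validating the fixed-edge-count random model:
    # targets drawn uniformly from the visible pool, action by fair coin
    "uniform_random": BehaviourParams(
        p_use_slot=0.8,
        p_add_given_both=0.5,
        add_density_slope=0.0,
        q_secure_provider=0.0,
        uniform_targets=True,
    ),
}


def sample_candidates(state: RoundState, focal, k: int,
                      rng: np.random.Generator) -> frozenset:
    """Uniform sample (without replacement) of up to ``k`` potential new recipients.

    The pool excludes the focal participant and its current recipients; a
    fresh sample is drawn every round, as in the experiment.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    excluded = state.recipients_of(focal) | {focal}
    pool = sorted(p for p in state.participants if p not in excluded)
    if not pool:
        return frozenset()
    if len(pool) <= k:
        return frozenset(pool)
    idx = rng.choice(len(pool), size=k, replace=False)
    return frozenset(pool[i] for i in idx)


def _pick_uniform(pool: Sequence, rng: np.random.Generator):
    return pool[int(rng.integers(len(pool)))]


def _split_by_sign(pool: Iterable, values: Mapping, focal_value: float):
    """Partition pool into strictly-lower / equal / strictly-higher of `values`."""
    lower, equal, higher = [], [], []
    for t in pool:
        v = values[t]
        (lower if v < focal_value else higher if v > focal_value else equal).append(t)
    return lower, equal, higher


def _biased_side_choice(pool: Sequence, values: Mapping, focal_value: float,
                        q_lower: float, rng: np.random.Generator):
    """Pick a target whose value is strictly lower with probability ``q_lower``.

    ``q_lower = 1/2`` encodes indifference and draws uniformly over the
    whole pool.  Otherwise the biased coin is exercised only when both
    strict sides offer a target, so the relative frequency of lower- versus
    higher-valued targets among the chosen ones equals ``q_lower`` by
    construction.  When only one strict side exists the agent settles for an
    equal-valued target (invisible to sign-based preference statistics) or,
    failing that, renounces the slot and ``None`` is returned.
    """
    lower, equal, higher = _split_by_sign(pool, values, focal_value)
    if lower and higher:
        chosen = lower if rng.random() < q_lower else higher
        return _pick_uniform(sorted(chosen), rng)
    if equal:
        return _pick_uniform(sorted(equal), rng)
    return None


def _removal_choice(pool: Sequence, payoffs: Mapping, gens: Mapping,
                    focal_payoff: float, focal_g: float,
                    q_higher_payoff: float, q_more_generous: float,
                    rng: np.random.Generator):
    """Removal target: payoff side first, then generosity side within it.

    The payoff comparison is the dominant, most consistent bias, so it is
    drawn first; the generosity bias is then applied inside the chosen
    payoff subpool.  At each stage ``q = 1/2`` encodes indifference (the
    stage passes its pool through untouched); otherwise the biased coin is
    exercised only when both strict sides are populated (falling back to
    equal-valued targets), so the sign statistics of executed removals match
    the configured probabilities; a slot with no acceptable target is
    renounced (``None``).
    """
    def g_choice(subpool):
        """Generosity-stage pick within one payoff side, or None if the side
        offers neither a strict choice nor an equal-generosity target."""
        lo_g, eq_g, hi_g = _split_by_sign(subpool, gens, focal_g)
        if lo_g and hi_g:
            chosen = hi_g if rng.random() < q_more_generous else lo_g
            return _pick_uniform(sorted(chosen), rng)
        if eq_g:
            return _pick_uniform(sorted(eq_g), rng)
        return None

    def g_viable(subpool):
        lo_g, eq_g, hi_g = _split_by_sign(subpool, gens, focal_g)
        return bool((lo_g and hi_g) or eq_g)

    lo_pi, eq_pi, hi_pi = _split_by_sign(pool, payoffs, focal_payoff)
    # viability of both payoff sides is established *before* any coin is
    # drawn, so renounced slots are independent of the coins and the sign
    # statistics of executed removals are exactly Bernoulli(q) on both axes
    if lo_pi and hi_pi and g_viable(lo_pi) and g_viable(hi_pi):
        subpool = hi_pi if rng.random() < q_higher_payoff else lo_pi
        return g_choice(subpool)
    if eq_pi:
        return g_choice(eq_pi)
    return None


def choose_updates(view: VisibleSets, focal, focal_g: int, focal_payoff: int,
                   stats: Mapping, params: BehaviourParams, config: SessionConfig,
                   rng: np.random.Generator) -> list[LinkUpdate]:
    """Decide up to ``max_updates_per_round`` link updates for one agent.

    ``stats`` maps every visible node to its displayed ``(g, payoff)`` pair
    from the previous round.  The returned updates are valid against the
    view: additions never target current recipients, removals always do.
    In the recipient-only treatment ``view`` carries no provider
    information, so decisions are structurally independent of who provides
    to the focal participant.
    """
    reciprocal = view.providers is not None
    gens = {t: stats[t][0] for t in stats}
    payoffs = {t: stats[t][1] for t in stats}

    addable_candidates = set(view.candidates)
    addable_providers = set(view.providers) if reciprocal else set()
    removable_plain = set(view.recipients)
    removable_recip = set(view.reciprocals) if reciprocal else set()

    n = config.n_participants
    # displayed (previous-round) values stay fixed for the whole round; only
    # the add-vs-remove drift tracks the agent's provisional out-degree
    drift_g = focal_g
    updates: list[LinkUpdate] = []
    for _ in range(config.max_updates_per_round):
        if rng.random() >= params.p_use_slot:
            continue  # renounced slot
        can_add = bool(addable_candidates or addable_providers)
        can_remove = bool(removable_plain or removable_recip)
        if not (can_add or can_remove):
            continue
        if can_add and can_remove:
            p_add = float(np.clip(
                params.p_add_given_both - params.add_density_slope * drift_g / (n - 1),
                0.0, 1.0))
            do_add = rng.random() < p_add
        else:
            do_add = can_add
        if do_add:
            if (reciprocal and addable_providers
                    and (not addable_candidates or rng.random() < params.q_secure_provider)):
                pool: set = addable_providers
            else:
                pool = addable_candidates or addable_providers
            if params.uniform_targets:
                target = _pick_uniform(sorted(pool), rng)
            else:
                target = _biased_side_choice(sorted(pool), payoffs, focal_payoff,
                                             params.q_add_lower_payoff, rng)
            if target is None:
                continue  # no acceptable target on this side; slot renounced
            updates.append(LinkUpdate(actor=focal, target=target, action=Action.ADD))
            addable_candidates.discard(target)
            addable_providers.discard(target)
            drift_g += 1
        else:
            # choose sub-pool proportionally to size, then apply the pool's
            # own generosity bias direction
            n_plain, n_recip = len(removable_plain), len(removable_recip)
            use_recip = (n_recip > 0 and
                         (n_plain == 0 or rng.random() < n_recip / (n_plain + n_recip)))
            if use_recip:
                pool = removable_recip
                q_more = params.q_remove_more_generous_reciprocal
            else:
                pool = removable_plain
                q_more = 1.0 - params.q_remove_less_generous
            if params.uniform_targets:
                target = _pick_uniform(sorted(pool), rng)
            else:
                target = _removal_choice(sorted(pool), payoffs, gens, focal_payoff,
                                         focal_g, params.q_remove_higher_payoff,
                                         q_more, rng)
            if target is None:
                continue  # slot renounced
            updates.append(LinkUpdate(actor=focal, target=target, action=Action.REMOVE))
            pool.discard(target)
            drift_g -= 1
    return updates


def _agent_rng(seed: int, round_index: int, agent_index: int) -> np.random.Generator:
    # one deterministic stream per (round, agent); independent of loop order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(round_index, agent_index)))


def simulate_session(config: SessionConfig, params: BehaviourParams,
                     seed: int) -> Session:
    """Run one complete synthetic session.

    Round 0 is the empty network; in each subsequent round every agent draws
    a fresh candidate sample, sees its treatment-dependent view of the
    previous round, chooses updates, and all updates are applied
    simultaneously under strict validation.  Identical ``(config, params,
    seed)`` yield identical sessions.
    """
    states = [RoundState.initial(config)]
    events: list[LoggedUpdate] = []
    for t in range(1, config.n_rounds + 1):
        prev = states[-1]
        per_actor: dict = {}
        for i, agent in enumerate(prev.participants):
            rng = _agent_rng(seed, t, i)
            cand = sample_candidates(prev, agent, config.candidate_sample_size, rng)
            view = visible_sets(prev, agent, config.treatment, cand)
            visible = set(view.recipients) | set(view.candidates)
            if view.providers is not None:
                visible |= set(view.providers) | set(view.reciprocals)
            stats = {p: (prev.g[p], prev.round_payoff[p]) for p in visible}
            per_actor[agent] = choose_updates(
                view, agent, prev.g[agent], prev.round_payoff[agent],
                stats, params, config, rng)
        result = validate_and_apply_round(prev, per_actor, config, strict=True)
        states.append(result.state)
        events.extend(LoggedUpdate(round=t, actor=u.actor, target=u.target,
                                   action=u.action) for u in result.applied)
    return Session(
        config=config, rounds=states, events=events,
        metadata={"generator": "coopnet.simulate.simulate_session",
                  "seed": int(seed),
                  "params": {f.name: getattr(params, f.name) for f in fields(params)}},
    )
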