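"""Session-level network statistics.

Covers the density/generosity series and its stationary regime, direct
reciprocation (bidirectional-link fraction) with a fixed-edge-count random
null, behavioural-type series, and the per-participant coupling between
recipient and provider counts (Kendall's tau-b).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats

from .core import DomainError, RoundState, Session, behavioural_type, classify_type

logger = logging.getLogger(__name__)


def normalized_generosity(g: int, n: int) -> float:
    """Generosity as the fraction ``g / (n - 1)`` of *other* participants helped."""
    if n < 2:
        raise DomainError("session size must be >= 2")
    if not 0 <= g <= n - 1:
        raise DomainError(f"g={g} outside 0..{n - 1}")
    return g / (n - 1)


def mean_generosity_series(session: Session) -> np.ndarray:
    """Per-round mean normalized generosity (network density); round 0 is 0."""
    n = len(session.participants)
    return np.array([
        float(np.mean([normalized_generosity(state.g[p], n) for p in state.participants]))
        for state in session.rounds
    ])


def bidirectional_fraction(edges: Iterable[tuple], mode: str = "links") -> float:
    """Fraction of directed links whose reverse link also exists.

    ``mode="links"`` counts each edge of a reciprocated pair (the
    experiment's measure of direct reciprocation); ``mode="dyads"`` counts
    connected unordered pairs instead, of which the reciprocated ones are the
    numerator.
    """
    edge_set = set(edges)
    if not edge_set:
        raise DomainError("bidirectional fraction undefined on an empty edge set")
    recip = sum(1 for (i, j) in edge_set if (j, i) in edge_set)
    if mode == "links":
        return recip / len(edge_set)
    if mode == "dyads":
        dyads = {frozenset(e) for e in edge_set}
        return (recip // 2) / len(dyads)
    raise DomainError(f"unknown mode {mode!r}")


def bidirectional_series(session: Session) -> list[float | None]:
    """Per-round bidirectional fraction; ``None`` for empty-network rounds."""
    out: list[float | None] = []
    for state in session.rounds:
        out.append(bidirectional_fraction(state.edges) if state.edges else None)
    return out


def expected_reciprocity(n: int, m: int) -> float:
    """Closed-form expected bidirectional fraction of a uniform random
    directed graph with exactly ``m`` distinct edges on ``n`` nodes.

    Conditional on an edge (i, j) being present, its reverse occupies one of
    the remaining ``n(n-1) - 1`` slots with ``m - 1`` edges left, giving
    ``(m - 1) / (n(n-1) - 1)``.
    """
    total = n * (n - 1)
    if not 1 <= m <= total:
        raise DomainError(f"m={m} outside 1..{total}")
    return (m - 1) / (total - 1)


@dataclass(frozen=True)
class NullModelResult:
    """Monte Carlo reciprocity null for fixed (n, m), plus the closed form."""

    mean: float
    sd: float
    samples: np.ndarray
    expected: float

    def percentile_band(self, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
        return (float(np.percentile(self.samples, lo)),
                float(np.percentile(self.samples, hi)))


def reciprocity_null(n: int, m: int, reps: int = 10_000,
                     seed: int | np.random.Generator = 0) -> NullModelResult:
    """Sample the bidirectional fraction of uniform random m-edge digraphs.

    The null keeps only the observed edge count fixed (no self-loops,
    out-degrees unconstrained): each replicate draws ``m`` distinct ordered
    pairs uniformly from the ``n(n-1)`` possible ones.
    """
    total = n * (n - 1)
    if not 1 <= m <= total:
        raise DomainError(f"m={m} outside 1..{total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # encode ordered pair (i, j), i != j, as i * (n - 1) + (j if j < i else j - 1);
    # the reverse-edge index is then computable without materialising tuples
    idx = np.arange(total)
    i = idx // (n - 1)
    j_ = idx % (n - 1)
    j = np.where(j_ < i, j_, j_ + 1)
    reverse = j * (n - 1) + np.where(i < j, i, i - 1)
    samples = np.empty(reps)
    present = np.zeros(total, dtype=bool)
    for r in range(reps):
        chosen = rng.choice(total, size=m, replace=False)
        present[chosen] = True
        samples[r] = present[reverse[chosen]].sum() / m
        present[chosen] = False
    return NullModelResult(mean=float(samples.mean()), sd=float(samples.std(ddof=1)),
                           samples=samples, expected=expected_reciprocity(n, m))


def numerical_derivative(series: Sequence[float]) -> np.ndarray:
    """Central-difference derivative with one-sided differences at the endpoints."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 3:
        raise DomainError("series must have length >= 3")
    return np.gradient(arr)


def stationary_rounds(series: Sequence[float], threshold: float = 0.1) -> set[int]:
    """Rounds where the series has (approximately) stopped changing.

    A round is stationary when the absolute numerical derivative is below
    ``threshold`` (default 10%) of the maximum absolute derivative.  A
    constant series is stationary everywhere.
    """
    deriv = np.abs(numerical_derivative(series))
    peak = deriv.max()
    if peak == 0:
        return set(range(len(deriv)))
    return {int(t) for t in np.flatnonzero(deriv < threshold * peak)}


def stationary_average(series: Sequence[float], window: int = 5,
                       stationary: set[int] | None = None) -> float:
    """Mean of the final ``window`` values (the stationary-regime average).

    If ``stationary`` is given, warns when the averaging window extends
    outside the detected stationary rounds.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < window:
        raise DomainError(f"series of length {arr.size} shorter than window {window}")
    tail = set(range(arr.size - window, arr.size))
    if stationary is not None and not tail <= stationary:
        logger.warning("averaging window %s extends outside stationary rounds", sorted(tail))
    return float(arr[-window:].mean())


@dataclass(frozen=True)
class SeriesSummary:
    """A per-round series with its stationary regime and last-window average."""

    values: tuple[float, ...]
    stationary_rounds: frozenset[int]
    stationary_mean: float
    stationary_sd: float
    window: int = 5


def summarize_series(series: Sequence[float], window: int = 5) -> SeriesSummary:
    arr = np.asarray(series, dtype=float)
    stat = frozenset(stationary_rounds(arr))
    return SeriesSummary(
        values=tuple(float(v) for v in arr),
        stationary_rounds=stat,
        stationary_mean=stationary_average(arr, window=window, stationary=set(stat)),
        stationary_sd=float(arr[-window:].std(ddof=0)),
        window=window,
    )


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Tie-corrected Kendall rank correlation (tau-b) of two equal-length series.

    Returns ``None`` when either series has zero variance (tau undefined);
    such participants are excluded from session averages.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise DomainError("series must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    tau = scipy.stats.kendalltau(x, y, variant="b").statistic
    return None if math.isnan(tau) else float(tau)


def recipients_providers_tau(session: Session, skip_rounds: int = 0) -> dict:
    """Per-participant tau-b between the g and l time series, plus the mean.

    Quantifies the coupling between how much a participant gives and how
    much it receives over the session.  Zero-variance participants are
    excluded from the mean.
    """
    taus: dict = {}
    rounds = session.rounds[skip_rounds:]
    for p in session.participants:
        g_series = [s.g[p] for s in rounds]
        l_series = [s.l[p] for s in rounds]
        taus[p] = kendall_tau(g_series, l_series)
    defined = [t for t in taus.values() if t is not None]
    return {"per_participant": taus,
            "mean": float(np.mean(defined)) if defined else None,
            "n_defined": len(defined)}


def behavioural_type_series(session: Session) -> dict:
    """Per-round mean behavioural type L over non-isolated participants.

    Rounds in which every node is isolated (round 0 in particular) yield
    ``None``.  Also returns per-participant L values and type labels for the
    final round.
    """
    means: list[float | None] = []
    for state in session.rounds:
        vals = [behavioural_type(state.g[p], state.l[p]) for p in state.participants]
        defined = [v for v in vals if v is not None]
        means.append(float(np.mean(defined)) if defined else None)
    last = session.rounds[-1]
    final_L = {p: behavioural_type(last.g[p], last.l[p]) for p in last.participants}
    labels = {p: (None if L is None else classify_type(L)) for p, L in final_L.items()}
    return {"mean_series": means, "final_L": final_L, "final_labels": labels}


def session_summary(session: Session, window: int = 5,
                    null_reps: int = 2000, seed: int = 0) -> dict:
    """Headline metrics of one session, as a flat dictionary.

    Includes the stationary generosity and bidirectional fraction (last
    ``window`` rounds), the matched random-graph null for the final round's
    edge count, the mean behavioural type, and the mean recipients-providers
    tau.
    """
    gen = summarize_series(mean_generosity_series(session), window=window)
    bidir = bidirectional_series(session)
    bidir_tail = [v for v in bidir[-window:] if v is not None]
    n = len(session.participants)
    m = len(session.rounds[-1].edges)
    null = reciprocity_null(n, m, reps=null_reps, seed=seed) if m >= 1 else None
    types = behavioural_type_series(session)
    tau = recipients_providers_tau(session)
    L_tail = [v for v in types["mean_series"][-window:] if v is not None]
    return {
        "treatment": session.config.treatment.value,
        "n_participants": n,
        "n_rounds": session.n_rounds_played,
        "stationary_generosity": gen.stationary_mean,
        "stationary_rounds": sorted(gen.stationary_rounds),
        "stationary_bidirectional": float(np.mean(bidir_tail)) if bidir_tail else None,
        "null_expected_bidirectional": null.expected if null else None,
        "null_mean_bidirectional": null.mean if null else None,
        "null_sd_bidirectional": null.sd if null else None,
        "mean_L_stationary": float(np.mean(L_tail)) if L_tail else None,
        "type_counts": {t: sum(1 for v in types["final_labels"].values() if v == t)
                        for t in ("altruist", "fair", "egoist")},
        "mean_tau": tau["mean"],
    }


def pooled_treatment_summary(sessions: Sequence[Session], window: int = 5) -> dict:
    """Average participant-level stationary values within each session, then
    across sessions of the same treatment, so large sessions do not dominate."""
    by_treatment: dict[str, list[dict]] = {}
    for s in sessions:
        n = len(s.participants)
        tail = s.rounds[-window:]
        per_part_gen = [float(np.mean([normalized_generosity(st.g[p], n) for st in tail]))
                        for p in s.participants]
        Ls = []
        for p in s.participants:
            vals = [behavioural_type(st.g[p], st.l[p]) for st in tail]
            vals = [v for v in vals if v is not None]
            if vals:
                Ls.append(float(np.mean(vals)))
        bidir = [bidirectional_fraction(st.edges) for st in tail if st.edges]
        entry = {
            "generosity": float(np.mean(per_part_gen)),
            "mean_L": float(np.mean(Ls)) if Ls else None,
            "bidirectional": float(np.mean(bidir)) if bidir else None,
        }
        by_treatment.setdefault(s.config.treatment.value, []).append(entry)
    out = {}
    for tr, entries in by_treatment.items():
        out[tr] = {
            "n_sessions": len(entries),
            "generosity": float(np.mean([e["generosity"] for e in entries])),
            "mean_L": float(np.mean([e["mean_L"] for e in entries
                                     if e["mean_L"] is not None])),
            "bidirectional": float(np.mean([e["bidirectional"] for e in entries
                                            if e["bidirectional"] is not None])),
        }
    return out
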