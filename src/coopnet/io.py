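"""Serialization, dataset adapters and fixtures.

A session is stored as a single self-describing JSON file (config + per-round
edge lists + event log + metadata); sessions are small (at most a few dozen
nodes, 60 rounds) so one file per session is comfortable.  Reading a session
replays its event log from the empty network under strict validation and
checks the result against every stored round, so a file that loads is
guaranteed internally consistent.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from . import __version__
from .core import (
    Action,
    DomainError,
    LoggedUpdate,
    RoundState,
    Session,
    SessionConfig,
    Treatment,
    replay,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


class SessionFormatError(DomainError):
    """A session file is malformed or violates a session invariant."""


def _config_to_dict(config: SessionConfig) -> dict:
    return {
        "n_participants": config.n_participants,
        "n_rounds": config.n_rounds,
        "benefit_b": config.benefit_b,
        "cost_c": config.cost_c,
        "endowment": config.endowment,
        "max_updates_per_round": config.max_updates_per_round,
        "treatment": config.treatment.value,
        "candidate_sample_size": config.candidate_sample_size,
    }


def write_session(session: Session, path: str | Path) -> Path:
    """Write one session as a self-describing JSON file.

    Logs the config hash, seed and package version of every artifact
    written, so any output can be traced back to its inputs.
    """
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config": _config_to_dict(session.config),
        "participants": list(session.participants),
        "metadata": dict(session.metadata, writer_version=__version__),
        "rounds": [sorted([list(e) for e in state.edges]) for state in session.rounds],
        "events": [[e.round, e.actor, e.target, e.action.value] for e in session.events],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    cfg_hash = hashlib.sha256(
        json.dumps(doc["config"], sort_keys=True).encode()).hexdigest()[:12]
    logger.info("wrote session %s (config %s, seed %r, coopnet %s)",
                path, cfg_hash, session.metadata.get("seed"), __version__)
    return path


def read_session(path: str | Path) -> Session:
    """Read a session file, replaying and validating the event log.

    Raises :class:`SessionFormatError` naming the offending round when the
    stored states cannot be reproduced from the events.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise SessionFormatError(f"{path}: not valid JSON ({err})") from None
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SessionFormatError(
            f"{path}: unsupported schema_version {doc.get('schema_version')!r}, "
            f"expected {SCHEMA_VERSION!r}")
    config = SessionConfig(**doc["config"])
    participants = tuple(doc["participants"])
    events = [LoggedUpdate(round=r, actor=a, target=t, action=Action(act))
              for r, a, t, act in doc["events"]]
    n_rounds = len(doc["rounds"]) - 1
    try:
        states = replay(config, participants, events, n_rounds)
    except DomainError as err:
        raise SessionFormatError(f"{path}: replay failed: {err}") from None
    for t, stored in enumerate(doc["rounds"]):
        stored_edges = {tuple(e) for e in stored}
        if stored_edges != states[t].edges:
            raise SessionFormatError(
                f"{path}: stored edges of round {t} differ from event-log replay")
    session = Session(config=config, rounds=states, events=events,
                      metadata=dict(doc.get("metadata", {})))
    session.validate()
    return session


def make_fixture_session() -> Session:
    """A deterministic, hand-scripted 5-participant, 8-round session.

    Built to exercise every analysis path on a tractable example: additions,
    removals, renounced slots, reciprocated pairs, and a final round that
    contains at least one altruist, one fair player and one egoist.  All of
    its metrics can be verified by hand.
    """
    config = SessionConfig(n_participants=5, n_rounds=8, treatment=Treatment.RECIPROCAL,
                           candidate_sample_size=4)
    script = {
        # round: [(actor, target, action), ...]
        1: [(0, 1, "add"), (0, 2, "add"), (1, 0, "add"), (2, 3, "add"), (3, 0, "add")],
        2: [(4, 0, "add"), (4, 1, "add"), (1, 2, "add"), (2, 0, "add"),
            (3, 0, "remove")],
        3: [(0, 3, "add"), (3, 4, "add")],
        4: [(1, 3, "add"), (2, 1, "add"), (4, 2, "add")],
        5: [(4, 1, "remove"), (1, 2, "remove")],
        6: [(0, 4, "add"), (2, 4, "add")],
        7: [(4, 0, "remove"), (4, 2, "remove"), (3, 1, "add")],
        8: [(0, 3, "remove"), (2, 0, "remove"), (1, 4, "add")],
    }
    events = [LoggedUpdate(round=r, actor=a, target=t, action=Action(act))
              for r in sorted(script) for a, t, act in script[r]]
    states = replay(config, config.participants, events, config.n_rounds)
    session = Session(config=config, rounds=states, events=events,
                      metadata={"label": "fixture", "generator": "coopnet.io.make_fixture_session"})
    session.validate()
    return session


_SUBFILE_TREATMENT = {letter: Treatment.RECIPIENT_ONLY for letter in "BCDE"}
_SUBFILE_TREATMENT.update({letter: Treatment.RECIPROCAL for letter in "FGHIJ"})

_EXPECTED_COLUMNS = ["round", "actor", "target", "action"]


def read_deposited_dataset(directory: str | Path) -> list[Session]:
    """Read an unpacked deposited-experiment directory into Sessions.

    Expects one event CSV per session named after the dataset's sub-file
    letters — B, C, D, E for the recipient-only treatment and F, G, H, I, J
    for the reciprocal treatment (e.g. ``B.csv`` or ``subfile_B.csv``) —
    with the columns ``round, actor, target, action`` (action ``add`` or
    ``remove``).  Each file is replayed from the empty network under strict
    validation.  Files in any other layout raise an explicit
    unsupported-format error listing the expected columns.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise SessionFormatError(f"{directory} is not a directory")
    sessions = []
    for path in sorted(directory.iterdir()):
        match = re.search(r"([B-J])\.(csv|txt)$", path.name, flags=re.IGNORECASE)
        if not match:
            continue
        letter = match.group(1).upper()
        treatment = _SUBFILE_TREATMENT[letter]
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not set(_EXPECTED_COLUMNS) <= set(
                    c.strip().lower() for c in reader.fieldnames):
                raise SessionFormatError(
                    f"{path}: unsupported column layout {reader.fieldnames}; "
                    f"expected columns {_EXPECTED_COLUMNS}")
            rows = [{k.strip().lower(): v.strip() for k, v in row.items()}
                    for row in reader]
        if not rows:
            raise SessionFormatError(f"{path}: no events")
        actors = sorted({r["actor"] for r in rows} | {r["target"] for r in rows})
        n_rounds = max(int(r["round"]) for r in rows)
        config = SessionConfig(n_participants=len(actors), n_rounds=n_rounds,
                               treatment=treatment)
        events = [LoggedUpdate(round=int(r["round"]), actor=r["actor"],
                               target=r["target"], action=Action(r["action"].lower()))
                  for r in rows]
        try:
            states = replay(config, tuple(actors), events, n_rounds)
        except DomainError as err:
            raise SessionFormatError(f"{path}: replay failed: {err}") from None
        session = Session(config=config, rounds=states, events=events,
                          metadata={"label": f"deposited:{letter}",
                                    "treatment": treatment.value, "source": str(path)})
        session.validate()
        sessions.append(session)
    if not sessions:
        raise SessionFormatError(
            f"{directory}: no session sub-files ([B-J].csv) found; "
            f"expected per-session event CSVs with columns {_EXPECTED_COLUMNS}")
    return sessions


def write_event_log(records: Iterable, path: str | Path) -> Path:
    """Write annotated events as CSV (round, actor, target, action, category, deltas)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["round", "actor", "target", "action", "category",
                         "delta_g", "delta_pi"])
        for e in records:
            writer.writerow([e.round, e.actor, e.target, e.action.value,
                             e.target_category, e.delta_g, e.delta_pi])
    return path


def export_snapshots(session: Session, out_dir: str | Path,
                     rounds: Sequence[int] = (0, 1, 2, 10, 60),
                     fmt: str = "graphml") -> list[Path]:
    """Export per-round network snapshots for external visualization.

    ``fmt`` is ``graphml`` or ``edgelist``; rounds beyond the session length
    are skipped with a log message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in rounds:
        if t >= len(session.rounds):
            logger.info("snapshot round %d beyond session length; skipped", t)
            continue
        state = session.rounds[t]
        graph = nx.DiGraph()
        graph.add_nodes_from(state.participants)
        graph.add_edges_from(state.edges)
        for p in state.participants:
            graph.nodes[p]["g"] = state.g[p]
            graph.nodes[p]["l"] = state.l[p]
            graph.nodes[p]["round_payoff"] = state.round_payoff[p]
        path = out_dir / f"round_{t:03d}.{ 'graphml' if fmt == 'graphml' else 'edgelist'}"
        if fmt == "graphml":
            nx.write_graphml(graph, path)
        elif fmt == "edgelist":
            with open(path, "w") as fh:
                for d, r in sorted(state.edges):
                    fh.write(f"{d}\t{r}\n")
        else:
            raise DomainError(f"unknown snapshot format {fmt!r}")
        written.append(path)
    return written
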