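"""Synthetic agents and sessions with controlled memory structure.

Every analysis stage can be exercised without animal data by simulating
agents whose turn choices have known statistics:

``iid``
    Memoryless chooser turning right with probability ``p_right``; the
    fair case P(R) = ½ is the null model under which every tetragram is
    expected at 6.25% and the step series is white.
``markov1``
    First-order chain parameterised by ``p_alternate``, the probability
    that the next turn differs from the previous one. p_alternate → 1
    yields pure alternation (LRLR…), → 0 pure repetition; 0.75 mimics the
    vertebrate alternation bias, 0.25 the fly repetition bias.
``markovk``
    Order-k chain with an explicit table mapping each length-k history to
    P(R); histories absent from the table fall back to ½.

Sessions wrap a turn sequence in zone-entry events: inter-entry gaps are
exponential (memoryless locomotion, i.e. entries form a Poisson process),
and arm labels walk the declared cyclic order so that
:func:`fmpy.ingest.visits_to_turns` recovers the agent's turn sequence
exactly — a tested round-trip contract. Choice and timing use independent
seeded streams, so the same agent seed yields the same turns regardless of
session parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ingest import ArmEntryLog, MazeGeometry, TurnSequence, ValidationError

__all__ = [
    "AgentSpec",
    "SessionSpec",
    "simulate_turns",
    "simulate_session",
    "simulate_cohort",
]

_AGENT_KINDS = ("iid", "markov1", "markovk")


@dataclass(frozen=True)
class AgentSpec:
    """A stochastic turn-choice process with a fixed seed."""

    kind: str
    p_right: float = 0.5
    p_alternate: float = 0.5
    order: int = 1
    table: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _AGENT_KINDS:
            raise ValidationError(f"unknown agent kind {self.kind!r}; one of {_AGENT_KINDS}")
        for name in ("p_right", "p_alternate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.kind == "markovk":
            if self.order < 1:
                raise ValidationError("markovk order must be >= 1")
            if self.table:
                for hist, p in self.table.items():
                    if len(hist) != self.order or set(hist) - set("LR"):
                        raise ValidationError(f"bad history key {hist!r}")
                    if not (0.0 <= p <= 1.0):
                        raise ValidationError(f"P(R|{hist})={p} outside [0, 1]")


@dataclass(frozen=True)
class SessionSpec:
    """Timing envelope of one simulated session."""

    duration: float = 3600.0
    mean_inter_entry: float = 3.6
    n_entries_target: int | None = None
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.mean_inter_entry <= 0:
            raise ValidationError("mean_inter_entry must be positive")


def _turn_rng(agent: AgentSpec) -> np.random.Generator:
    return np.random.default_rng(agent.seed)


def simulate_turns(agent: AgentSpec, n_turns: int) -> TurnSequence:
    """Draw a reproducible turn sequence of length ``n_turns`` from an agent.

    The first turn is uniform (for markov agents the first ``order`` turns
    are); subsequent turns follow the agent's law. Same spec + seed give
    identical output.
    """
    if n_turns < 0:
        raise ValidationError("n_turns must be >= 0")
    rng = _turn_rng(agent)
    sid = f"{agent.kind}-seed{agent.seed}"
    if n_turns == 0:
        return TurnSequence(sid, "")
    if agent.kind == "iid":
        draws = rng.random(n_turns) < agent.p_right
        turns = "".join("R" if d else "L" for d in draws)
    elif agent.kind == "markov1":
        out = ["R" if rng.random() < 0.5 else "L"]
        u = rng.random(n_turns - 1)
        for i in range(n_turns - 1):
            alternate = u[i] < agent.p_alternate
            prev = out[-1]
            out.append(("L" if prev == "R" else "R") if alternate else prev)
        turns = "".join(out)
    else:  # markovk
        k = agent.order
        table = agent.table or {}
        out = ["R" if rng.random() < 0.5 else "L" for _ in range(min(k, n_turns))]
        while len(out) < n_turns:
            hist = "".join(out[-k:])
            p_r = table.get(hist, 0.5)
            out.append("R" if rng.random() < p_r else "L")
        turns = "".join(out)
    return TurnSequence(sid, turns)


def simulate_session(
    agent: AgentSpec, session: SessionSpec, geom: MazeGeometry
) -> ArmEntryLog:
    """Wrap an agent's turns in a zone-entry log.

    Entry times accumulate exponential gaps; with ``n_entries_target`` unset
    the process is truncated at ``session.duration`` (expected entry count =
    duration / mean gap), otherwise exactly that many entries are produced.
    Arm labels are chosen so ``visits_to_turns(log, geom)`` returns exactly
    ``simulate_turns(agent, n_entries − 1)``.
    """
    time_rng = np.random.default_rng([int(agent.seed), 0x5E55])
    if session.n_entries_target is not None:
        if session.n_entries_target < 0:
            raise ValidationError("n_entries_target must be >= 0")
        gaps = time_rng.exponential(session.mean_inter_entry, session.n_entries_target)
        times = np.cumsum(gaps)
    else:
        # expected count plus generous headroom, then truncate at duration
        expect = session.duration / session.mean_inter_entry
        n_draw = int(expect + 10 * np.sqrt(expect) + 10)
        while True:
            gaps = time_rng.exponential(session.mean_inter_entry, n_draw)
            times = np.cumsum(gaps)
            if times[-1] >= session.duration:
                break
            n_draw *= 2
        times = times[times < session.duration]
    n_entries = times.size
    turns = simulate_turns(agent, max(0, n_entries - 1))

    ccw_symbol = "L" if geom.chirality == "ccw_is_left" else "R"
    pos = 0
    zones = [geom.arm_labels[0]] if n_entries else []
    for sym in turns.turns:
        pos = (pos + (1 if sym == ccw_symbol else -1)) % 3
        zones.append(geom.arm_labels[pos])
    return ArmEntryLog(session.subject_id, times, tuple(zones), session.duration)


def simulate_cohort(
    specs: Sequence[tuple[AgentSpec, SessionSpec]], geom: MazeGeometry
) -> list[ArmEntryLog]:
    """Simulate a reproducible cohort, one independent seeded stream per subject."""
    if not specs:
        raise ValidationError("empty cohort specification")
    ids = [sess.subject_id for _, sess in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate subject_id(s) {dupes}")
    return [simulate_session(agent, sess, geom) for agent, sess in specs]
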