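"""Reading zone-entry logs and deriving left/right turn sequences.

Automated Y-maze trackers emit an ordered stream of zone-entry events
(timestamp, zone label) per subject. Analysis operates on *turns*: a turn
is scored whenever the animal enters a different arm than the one it is
currently in. With three arms in a declared cyclic order, every non-self
arm transition is unambiguously one step "with" or "against" that order,
which a chirality flag maps onto the symbols L and R. The raw log is
therefore processed in three stages:

1. :func:`read_entry_log` — parse the tracker CSV into an
   :class:`ArmEntryLog`, validating time ordering.
2. :func:`collapse_visits` — drop non-arm zones (centre, outside) and merge
   consecutive re-entries into the same arm into a single visit.
3. :func:`visits_to_turns` — map consecutive visits to L/R symbols using a
   :class:`MazeGeometry`.

The tracker never records handedness, so the L/R convention is explicit
user configuration: published group statistics are reproduced up to mirror
symmetry regardless of the convention chosen.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "CsvDialect",
    "DEFAULT_DIALECT",
    "ArmEntryLog",
    "MazeGeometry",
    "TurnSequence",
    "read_entry_log",
    "read_turn_file",
    "turn_sequence_from_string",
    "collapse_visits",
    "visits_to_turns",
    "mirror",
    "write_entry_log",
]

TURN_ALPHABET = frozenset("LR")
_MIRROR = str.maketrans("LR", "RL")


class FormatError(ValueError):
    """Input file cannot be parsed in the declared dialect."""


class ValidationError(ValueError):
    """Input parses but violates a data invariant."""


@dataclass(frozen=True)
class CsvDialect:
    """Column naming and delimiter conventions of a tracker CSV export.

    Defaults match the documented interchange format: comma-separated with
    columns ``time_s`` (seconds from trial start) and ``zone``.
    ``time_scale`` multiplies raw time values into seconds (e.g. 0.001 for
    millisecond exports).
    """

    time_col: str = "time_s"
    zone_col: str = "zone"
    delimiter: str = ","
    time_scale: float = 1.0


DEFAULT_DIALECT = CsvDialect()


@dataclass
class ArmEntryLog:
    """Ordered zone-entry events for one subject's session."""

    subject_id: str
    times: np.ndarray
    zones: tuple[str, ...]
    session_duration: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.zones = tuple(str(z) for z in self.zones)
        if self.times.size != len(self.zones):
            raise ValidationError(
                f"{self.subject_id}: {self.times.size} times vs {len(self.zones)} zones"
            )
        if self.times.size and np.any(np.diff(self.times) < 0):
            bad = int(np.argmax(np.diff(self.times) < 0)) + 1
            raise ValidationError(
                f"{self.subject_id}: event times decrease at event index {bad} "
                f"(t={self.times[bad]:g} after t={self.times[bad - 1]:g})"
            )
        if self.times.size and np.any(self.times < 0):
            raise ValidationError(f"{self.subject_id}: negative event time")

    @property
    def n_events(self) -> int:
        return len(self.zones)


@dataclass(frozen=True)
class MazeGeometry:
    """Cyclic arm layout of a three-armed maze plus the handedness convention.

    ``arm_labels`` lists the arms in counter-clockwise order as seen from
    above. ``chirality`` states which turn symbol a counter-clockwise arm
    transition produces; flipping it mirrors every inferred sequence.
    ``non_arm_zones`` are tracker zones (centre, outside) dropped before
    turn inference.
    """

    arm_labels: tuple[str, str, str]
    chirality: str = "ccw_is_left"
    non_arm_zones: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm_labels", tuple(self.arm_labels))
        object.__setattr__(self, "non_arm_zones", frozenset(self.non_arm_zones))
        if len(self.arm_labels) != 3 or len(set(self.arm_labels)) != 3:
            raise ValidationError("geometry requires exactly 3 distinct arm labels")
        if self.chirality not in ("ccw_is_left", "ccw_is_right"):
            raise ValidationError(f"unknown chirality {self.chirality!r}")
        if self.non_arm_zones & set(self.arm_labels):
            raise ValidationError("non_arm_zones overlap arm labels")

    @property
    def zone_set(self) -> frozenset[str]:
        return frozenset(self.arm_labels) | self.non_arm_zones

    def mirrored(self) -> "MazeGeometry":
        other = "ccw_is_right" if self.chirality == "ccw_is_left" else "ccw_is_left"
        return replace(self, chirality=other)


@dataclass(frozen=True)
class TurnSequence:
    """An ordered sequence of L/R turn choices, optionally time-stamped."""

    subject_id: str
    turns: str
    turn_times: np.ndarray | None = None
    session_duration: float | None = None

    def __post_init__(self) -> None:
        if set(self.turns) - TURN_ALPHABET:
            bad = sorted(set(self.turns) - TURN_ALPHABET)
            raise ValidationError(f"{self.subject_id}: turn symbols {bad} not in {{L,R}}")
        if self.turn_times is not None:
            times = np.asarray(self.turn_times, dtype=float)
            object.__setattr__(self, "turn_times", times)
            if times.size != len(self.turns):
                raise ValidationError(
                    f"{self.subject_id}: {times.size} turn times for {len(self.turns)} turns"
                )
            if times.size and np.any(np.diff(times) < 0):
                raise ValidationError(f"{self.subject_id}: turn times not non-decreasing")

    def __len__(self) -> int:
        return len(self.turns)

    @property
    def n_turns(self) -> int:
        return len(self.turns)


def read_entry_log(
    source,
    dialect: CsvDialect = DEFAULT_DIALECT,
    subject_id: str | None = None,
    session_duration: float | None = None,
    zone_set: Iterable[str] | None = None,
) -> ArmEntryLog:
    """Parse a zone-entry CSV into an :class:`ArmEntryLog`.

    ``source`` may be a path or an open text stream. Rows must be ordered
    by time; a malformed time field raises :class:`FormatError` naming the
    first offending line (1-based, counting the header). If ``zone_set`` is
    given, unknown zone labels raise :class:`ValidationError`.
    """
    if subject_id is None:
        subject_id = Path(source).stem if isinstance(source, (str, Path)) else "subject"
    try:
        df = pd.read_csv(source, sep=dialect.delimiter)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{subject_id}: empty input, no events read", stacklevel=2)
        return ArmEntryLog(subject_id, np.empty(0), (), session_duration)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{subject_id}: unparseable CSV: {exc}") from exc

    missing = {dialect.time_col, dialect.zone_col} - set(df.columns)
    if missing:
        raise FormatError(
            f"{subject_id}: missing column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    if df.empty:
        warnings.warn(f"{subject_id}: no event rows", stacklevel=2)
        return ArmEntryLog(subject_id, np.empty(0), (), session_duration)

    times = pd.to_numeric(df[dialect.time_col], errors="coerce")
    if times.isna().any():
        # +2: header line plus 1-based numbering
        line = int(np.argmax(times.isna().to_numpy())) + 2
        raise FormatError(
            f"{subject_id}: unparseable time value "
            f"{df[dialect.time_col].iloc[line - 2]!r} at line {line}"
        )
    times = times.to_numpy(dtype=float) * dialect.time_scale
    decreasing = np.diff(times) < 0
    if decreasing.any():
        line = int(np.argmax(decreasing)) + 3  # row after the drop, 1-based + header
        raise ValidationError(f"{subject_id}: rows out of time order at line {line}")

    zones = tuple(str(z).strip() for z in df[dialect.zone_col])
    if zone_set is not None:
        unknown = sorted(set(zones) - set(zone_set))
        if unknown:
            raise ValidationError(f"{subject_id}: unknown zone label(s) {unknown}")
    return ArmEntryLog(subject_id, times, zones, session_duration)


def turn_sequence_from_string(
    text: str, subject_id: str = "subject", session_duration: float | None = None
) -> TurnSequence:
    """Build a :class:`TurnSequence` from a plain turn string like ``"LRLR"``.

    Whitespace and commas are ignored; case is normalised.
    """
    cleaned = "".join(text.upper().split()).replace(",", "")
    return TurnSequence(subject_id, cleaned, None, session_duration)


def read_turn_file(source, subject_id: str | None = None) -> list[TurnSequence]:
    """Read pre-extracted turn strings, one subject per non-empty line.

    Lines may be ``id,LRLR...`` or a bare turn string (subjects are then
    numbered from 1, or named ``subject_id`` if a single line).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        default_id = Path(source).stem
    else:
        text = source.read()
        default_id = "subject"
    if subject_id is not None:
        default_id = subject_id
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    out: list[TurnSequence] = []
    for i, ln in enumerate(lines, start=1):
        if "," in ln:
            sid, turns = ln.split(",", 1)
            out.append(turn_sequence_from_string(turns, sid.strip()))
        else:
            sid = default_id if len(lines) == 1 else f"{default_id}_{i}"
            out.append(turn_sequence_from_string(ln, sid))
    return out


def collapse_visits(log: ArmEntryLog, geom: MazeGeometry) -> ArmEntryLog:
    """Reduce raw zone events to arm visits.

    Non-arm zones are removed and consecutive duplicate arm entries are
    merged into a single visit keeping the first timestamp. Idempotent.
    Zones that are neither arms nor declared non-arm zones raise
    :class:`ValidationError`.
    """
    arms = set(geom.arm_labels)
    unknown = sorted(set(log.zones) - geom.zone_set)
    if unknown:
        raise ValidationError(f"{log.subject_id}: unknown zone label(s) {unknown}")
    times: list[float] = []
    zones: list[str] = []
    for t, z in zip(log.times, log.zones):
        if z not in arms:
            continue
        if zones and zones[-1] == z:
            continue
        times.append(float(t))
        zones.append(z)
    return ArmEntryLog(log.subject_id, np.asarray(times), tuple(zones), log.session_duration)


def visits_to_turns(log: ArmEntryLog, geom: MazeGeometry) -> TurnSequence:
    """Infer the L/R turn sequence from a collapsed arm-visit log.

    For consecutive visits i → j, moving one position *along* the declared
    counter-clockwise arm order emits the chirality-defined symbol; moving
    against it emits the other. n visits yield max(0, n − 1) turns, each
    stamped with the destination visit's time.
    """
    idx = {label: k for k, label in enumerate(geom.arm_labels)}
    unknown = sorted(set(log.zones) - set(geom.arm_labels))
    if unknown:
        raise ValidationError(f"{log.subject_id}: non-arm zone(s) {unknown}; collapse first")
    ccw_symbol = "L" if geom.chirality == "ccw_is_left" else "R"
    cw_symbol = "R" if ccw_symbol == "L" else "L"
    turns: list[str] = []
    times: list[float] = []
    for k in range(1, log.n_events):
        delta = (idx[log.zones[k]] - idx[log.zones[k - 1]]) % 3
        if delta == 0:
            raise ValidationError(
                f"{log.subject_id}: repeated arm {log.zones[k]!r} at event {k}; "
                "collapse_visits must be applied first"
            )
        turns.append(ccw_symbol if delta == 1 else cw_symbol)
        times.append(float(log.times[k]))
    return TurnSequence(
        log.subject_id, "".join(turns), np.asarray(times), log.session_duration
    )


def mirror(seq: TurnSequence) -> TurnSequence:
    """Swap every L↔R; times and metadata preserved. An involution."""
    return replace(seq, turns=seq.turns.translate(_MIRROR))


def write_entry_log(log: ArmEntryLog, path, dialect: CsvDialect = DEFAULT_DIALECT) -> None:
    """Write an :class:`ArmEntryLog` in the same CSV dialect `read_entry_log` reads."""
    df = pd.DataFrame(
        {dialect.time_col: log.times / dialect.time_scale, dialect.zone_col: log.zones}
    )
    df.to_csv(path, index=False, sep=dialect.delimiter)
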