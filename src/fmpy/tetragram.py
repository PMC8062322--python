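"""Overlapping tetragram analysis of turn sequences.

A tetragram is a window of four consecutive L/R turn choices; there are
2^4 = 16 of them. Sliding a width-4, stride-1 window along a turn sequence
of T turns yields max(0, T − 3) tetragrams, and each tetragram's relative
frequency is reported as a percentage of that window count. Under a
memoryless fair-choice agent every tetragram is expected at 6.25%
(:data:`CHANCE_PCT`). Two motif classes carry special weight in working
memory assays: *alternations* (LRLR, RLRL), the dominant vertebrate search
motif, and *repetitions* (LLLL, RRRR), the dominant fly motif.

Time-resolved strategy is described by splitting a session into equal time
bins (conventionally six 10-minute bins of a 1-hour trial) and tabulating
tetragrams within each bin independently; windows never straddle a bin
boundary, so bins are independent and re-composable. The first 10 minutes
give the "immediate" strategy; the whole session gives the "global" one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import TurnSequence, ValidationError, _MIRROR

__all__ = [
    "ALL_TETRAGRAMS",
    "ALTERNATIONS",
    "REPETITIONS",
    "CHANCE_PCT",
    "mirror_tetragram",
    "classify_tetragram",
    "extract_tetragrams",
    "TetragramTable",
    "tetragram_table",
    "BinnedStrategy",
    "bin_by_time",
    "immediate_and_global",
    "tidy_frame",
]

#: The 16 tetragrams, ordered by their signed step code (−8 … −1, +1 … +8).
ALL_TETRAGRAMS: tuple[str, ...] = (
    "LLLL", "LLLR", "LLRL", "LRLL", "RLLL", "LLRR", "LRRL", "LRLR",
    "RLRL", "RLLR", "RRLL", "LRRR", "RLRR", "RRLR", "RRRL", "RRRR",
)
ALTERNATIONS: tuple[str, str] = ("LRLR", "RLRL")
REPETITIONS: tuple[str, str] = ("LLLL", "RRRR")
#: Expected percentage of each tetragram under memoryless fair choice.
CHANCE_PCT: float = 100.0 / 16

assert set(ALL_TETRAGRAMS) == {"".join(p) for p in product("LR", repeat=4)}


def mirror_tetragram(t: str) -> str:
    """L↔R image of a tetragram (e.g. LLRL → RRLR)."""
    return t.translate(_MIRROR)


def classify_tetragram(t: str) -> str:
    """Return 'alternation', 'repetition' or 'other'."""
    if t in ALTERNATIONS:
        return "alternation"
    if t in REPETITIONS:
        return "repetition"
    return "other"


def _turn_string(seq: TurnSequence | str) -> str:
    return seq.turns if isinstance(seq, TurnSequence) else seq


def extract_tetragrams(seq: TurnSequence | str) -> list[str]:
    """All overlapping tetragrams of a turn sequence, in order.

    Width-4 sliding window with stride 1; a sequence of T turns yields
    max(0, T − 3) tetragrams.
    """
    turns = _turn_string(seq)
    return [turns[i : i + 4] for i in range(max(0, len(turns) - 3))]


@dataclass
class TetragramTable:
    """Counts and percentages of the 16 tetragrams over one analysis window.

    ``total_turns`` is the number of turns contributing to the window;
    ``n_windows`` (= Σ counts = max(0, total_turns − 3) for a contiguous
    window) is the percentage denominator. With no windows the table is
    flagged undefined and percentages are NaN.
    """

    counts: dict[str, int]
    total_turns: int
    window: str = "session"

    def __post_init__(self) -> None:
        full = {t: 0 for t in ALL_TETRAGRAMS}
        unknown = set(self.counts) - set(ALL_TETRAGRAMS)
        if unknown:
            raise ValidationError(f"unknown tetragram(s) {sorted(unknown)}")
        full.update({t: int(c) for t, c in self.counts.items()})
        self.counts = full

    @property
    def n_windows(self) -> int:
        return sum(self.counts.values())

    @property
    def defined(self) -> bool:
        return self.n_windows > 0

    def pct(self, t: str) -> float:
        if not self.defined:
            return math.nan
        return 100.0 * self.counts[t] / self.n_windows

    @property
    def percentages(self) -> dict[str, float]:
        return {t: self.pct(t) for t in ALL_TETRAGRAMS}

    @property
    def alternation_pct(self) -> float:
        return self.pct("LRLR") + self.pct("RLRL")

    @property
    def repetition_pct(self) -> float:
        return self.pct("LLLL") + self.pct("RRRR")

    def mirrored(self) -> "TetragramTable":
        return TetragramTable(
            {mirror_tetragram(t): c for t, c in self.counts.items()},
            self.total_turns,
            self.window,
        )


def tetragram_table(seq: TurnSequence | str, window: str = "session") -> TetragramTable:
    """Tabulate the 16 overlapping tetragram frequencies of a turn sequence.

    Sequences shorter than 4 turns give an all-zero table flagged undefined
    (``defined`` is False, percentages NaN).
    """
    turns = _turn_string(seq)
    counts: dict[str, int] = {}
    for t in extract_tetragrams(turns):
        counts[t] = counts.get(t, 0) + 1
    return TetragramTable(counts, total_turns=len(turns), window=window)


@dataclass
class BinnedStrategy:
    """Per-time-bin tetragram tables covering a session contiguously."""

    bins: list[TetragramTable]
    n_bins: int
    bin_duration: float
    source: TurnSequence

    def __iter__(self):
        return iter(self.bins)


def bin_by_time(seq: TurnSequence, n_bins: int = 6) -> BinnedStrategy:
    """Split a session into ``n_bins`` equal time bins and tabulate each.

    Turns are assigned to bins by their timestamp; tetragram windows are
    computed within each bin independently, never straddling a boundary.
    Requires ``turn_times``.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if seq.turn_times is None:
        raise ValidationError(
            f"{seq.subject_id}: no turn times; use tetragram_table for "
            "whole-session analysis"
        )
    duration = seq.session_duration
    if duration is None:
        duration = float(seq.turn_times[-1]) if len(seq) else 0.0
    bin_duration = duration / n_bins if n_bins else 0.0
    tables: list[TetragramTable] = []
    for b in range(n_bins):
        if duration > 0 and len(seq):
            ids = np.minimum((seq.turn_times / bin_duration).astype(int), n_bins - 1)
            mask = ids == b
            turns_b = "".join(np.array(list(seq.turns))[mask]) if mask.any() else ""
        else:
            turns_b = seq.turns if b == 0 else ""
        tables.append(tetragram_table(turns_b, window=f"bin{b + 1}"))
    return BinnedStrategy(tables, n_bins, bin_duration, seq)


def immediate_and_global(
    strategy: BinnedStrategy, immediate_window: float = 600.0
) -> tuple[TetragramTable, TetragramTable]:
    """The short-horizon vs whole-session strategy tables.

    ``immediate`` tabulates turns within the first ``immediate_window``
    seconds (10 minutes by default); ``global`` tabulates the whole session.
    Sessions shorter than the immediate window make the two coincide (with
    a warning).
    """
    seq = strategy.source
    global_table = tetragram_table(seq, window="global")
    duration = seq.session_duration
    if duration is None and seq.turn_times is not None and len(seq):
        duration = float(seq.turn_times[-1])
    if duration is not None and duration < immediate_window:
        warnings.warn(
            f"{seq.subject_id}: session ({duration:g}s) shorter than the "
            f"immediate window ({immediate_window:g}s); immediate = whole session",
            stacklevel=2,
        )
        immediate = tetragram_table(seq, window="immediate")
        return immediate, global_table
    if seq.turn_times is None:
        raise ValidationError(f"{seq.subject_id}: immediate strategy needs turn times")
    # half-open [0, window), matching the time-bin convention, so that the
    # immediate table equals bin 1 when bin_duration == immediate_window
    mask = seq.turn_times < immediate_window
    turns_im = "".join(np.array(list(seq.turns))[mask]) if len(seq) and mask.any() else ""
    return tetragram_table(turns_im, window="immediate"), global_table


def tidy_frame(tables: Sequence[TetragramTable], subject_id: str) -> pd.DataFrame:
    """Long-format table: one row per (subject, window, tetragram)."""
    rows = []
    for tab in tables:
        for t in ALL_TETRAGRAMS:
            rows.append(
                {
                    "subject": subject_id,
                    "window": tab.window,
                    "tetragram": t,
                    "class": classify_tetragram(t),
                    "count": tab.counts[t],
                    "percent": tab.pct(t),
                }
            )
    return pd.DataFrame(rows)
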