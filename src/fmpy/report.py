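"""End-to-end per-subject analysis and tidy cohort exports.

:func:`analyze_subject` runs the full deterministic pipeline on one
subject — collapse zone events, infer turns, tabulate tetragrams (global,
time-binned, immediate), compute uncertainty measures, encode the step
series, apply the missing-data rule, and count significant ACF lags on the
cumulative sum — and returns a :class:`SubjectSummary`. Subjects excluded
by the missing-data rule keep their row, flagged, never silently dropped.

Group-level inference (mixed models, ANOVA, post hocs) is deliberately not
performed here: :func:`cohort_table` exports a tidy long-format table —
one (subject, group, window, metric, value) row per measurement, with
``total_turns`` as the locomotor covariate — ready for external
statistical software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import infotheory, tetragram, timeseries
from .ingest import ArmEntryLog, MazeGeometry, TurnSequence, ValidationError
from .ingest import collapse_visits, visits_to_turns

__all__ = ["AnalysisConfig", "SubjectSummary", "analyze_subject", "cohort_table", "summary_frame"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-subject pipeline.

    Defaults correspond to hour-long animal sessions: six 10-minute bins,
    the first 1000 arm entries, a 250-step target with at most 10 zero-filled
    steps, and the large-lag Bartlett 95% band over the first 20 lags. For
    5-minute human sessions use ``max_entries=100``, ``target_steps=25`` and
    a shorter ``immediate_window``.
    """

    n_bins: int = 6
    max_entries: int = 1000
    target_steps: int = 250
    max_missing: int = 10
    band: str = "large_lag_bartlett"
    max_lag: int = 20
    n_significant_first: int = 20
    immediate_window: float = 600.0
    overlapping_steps: bool = False


@dataclass
class SubjectSummary:
    """One subject's full metric set; one row of the cohort table."""

    subject_id: str
    total_turns: int
    tetragram_pct: dict[str, float]
    alternation_pct: float
    repetition_pct: float
    L1: float
    L3: float
    L4: float
    relative_complement: float
    n_significant_lags: float
    excluded: bool
    n_missing_filled: int
    bins: tetragram.BinnedStrategy | None = field(default=None, repr=False)
    immediate: tetragram.TetragramTable | None = field(default=None, repr=False)
    global_table: tetragram.TetragramTable | None = field(default=None, repr=False)
    steps: timeseries.StepSeries | None = field(default=None, repr=False)
    acf: timeseries.ACFResult | None = field(default=None, repr=False)


def _entropy_metrics(seq: TurnSequence) -> tuple[float, float, float, float]:
    if len(seq) < 4:
        return (math.nan,) * 4
    h1 = infotheory.uncertainty(infotheory.ngram_distribution(seq, 1))
    h3 = infotheory.uncertainty(infotheory.ngram_distribution(seq, 3))
    summary = infotheory.uncertainty_summary(seq)
    return h1, h3, summary.L4, summary.relative_complement


def analyze_subject(
    subject: ArmEntryLog | TurnSequence,
    geom: MazeGeometry | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> SubjectSummary:
    """Run the full pipeline for one subject.

    Accepts either a raw :class:`ArmEntryLog` (requires ``geom``) or an
    already-extracted :class:`TurnSequence`. Deterministic: identical inputs
    and config give identical summaries.
    """
    if isinstance(subject, ArmEntryLog):
        if geom is None:
            raise ValidationError("geometry required to analyse a zone-entry log")
        seq = visits_to_turns(collapse_visits(subject, geom), geom)
    else:
        seq = subject

    global_table = tetragram.tetragram_table(seq, window="global")
    bins = immediate = None
    if seq.turn_times is not None and len(seq):
        bins = tetragram.bin_by_time(seq, config.n_bins)
        immediate, global_table = tetragram.immediate_and_global(
            bins, config.immediate_window
        )

    h1, h3, l4, rel = _entropy_metrics(seq)

    steps = timeseries.apply_missing_rule(
        timeseries.encode_steps(seq, config.max_entries, config.overlapping_steps),
        config.target_steps,
        config.max_missing,
    )
    n_sig: float = math.nan
    acf_result = None
    if not steps.excluded:
        walk = timeseries.cumulative_sum(steps)
        if np.var(walk) > 0 and walk.size >= config.max_lag + 2:
            acf_result = timeseries.confidence_band(
                timeseries.acf(walk, config.max_lag), config.band
            )
            n_sig = float(
                timeseries.significant_lags(acf_result, config.n_significant_first)
            )

    return SubjectSummary(
        subject_id=seq.subject_id,
        total_turns=len(seq),
        tetragram_pct=global_table.percentages,
        alternation_pct=global_table.alternation_pct,
        repetition_pct=global_table.repetition_pct,
        L1=h1,
        L3=h3,
        L4=l4,
        relative_complement=rel,
        n_significant_lags=n_sig,
        excluded=steps.excluded,
        n_missing_filled=steps.n_missing_filled,
        bins=bins,
        immediate=immediate,
        global_table=global_table,
        steps=steps,
        acf=acf_result,
    )


def _metric_rows(summary: SubjectSummary, group: str) -> list[dict]:
    rows = []

    def add(window: str, metric: str, value) -> None:
        rows.append(
            {
                "subject": summary.subject_id,
                "group": group,
                "window": window,
                "metric": metric,
                "value": value,
            }
        )

    add("global", "total_turns", summary.total_turns)
    add("global", "excluded", int(summary.excluded))
    add("global", "n_missing_filled", summary.n_missing_filled)
    for t, p in summary.tetragram_pct.items():
        add("global", f"pct_{t}", p)
    add("global", "alternation_pct", summary.alternation_pct)
    add("global", "repetition_pct", summary.repetition_pct)
    for name in ("L1", "L3", "L4", "relative_complement"):
        add("global", name, getattr(summary, name))
    add("global", "n_significant_lags", summary.n_significant_lags)
    if summary.immediate is not None:
        add("immediate", "alternation_pct", summary.immediate.alternation_pct)
        add("immediate", "repetition_pct", summary.immediate.repetition_pct)
    if summary.bins is not None:
        for tab in summary.bins:
            add(tab.window, "alternation_pct", tab.alternation_pct)
            add(tab.window, "repetition_pct", tab.repetition_pct)
    return rows


def cohort_table(
    summaries: list[SubjectSummary], group_labels: list[str] | None = None
) -> pd.DataFrame:
    """Tidy long-format cohort export for external mixed-model software.

    Columns (subject, group, window, metric, value); one row per
    measurement. ``group_labels`` must align with ``summaries`` (a single
    unnamed group by default).
    """
    if not summaries:
        raise ValidationError("no subject summaries to tabulate")
    if group_labels is None:
        group_labels = ["all"] * len(summaries)
    if len(group_labels) != len(summaries):
        raise ValidationError(
            f"{len(group_labels)} group labels for {len(summaries)} summaries"
        )
    rows: list[dict] = []
    for summary, group in zip(summaries, group_labels):
        rows.extend(_metric_rows(summary, group))
    return pd.DataFrame(rows)


def summary_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """Wide-format table: one row per subject, one column per global metric."""
    if not summaries:
        raise ValidationError("no subject summaries to tabulate")
    rows = []
    for s in summaries:
        row: dict = {
            "subject": s.subject_id,
            "total_turns": s.total_turns,
            "alternation_pct": s.alternation_pct,
            "repetition_pct": s.repetition_pct,
            "L1": s.L1,
            "L3": s.L3,
            "L4": s.L4,
            "relative_complement": s.relative_complement,
            "n_significant_lags": s.n_significant_lags,
            "excluded": s.excluded,
            "n_missing_filled": s.n_missing_filled,
        }
        row.update({f"pct_{t}": p for t, p in s.tetragram_pct.items()})
        rows.append(row)
    return pd.DataFrame(rows)
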