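"""YAML configuration mirroring the CLI flags.

A config file has up to three sections::

    geometry:
      arms: [A, B, C]          # counter-clockwise order
      chirality: ccw_is_left   # or ccw_is_right
      non_arm_zones: [centre]
    dialect:
      time_col: time_s
      zone_col: zone
      delimiter: ","
      time_scale: 1.0
    analysis:
      n_bins: 6
      max_entries: 1000
      target_steps: 250
      max_missing: 10
      band: large_lag_bartlett
      max_lag: 20
      immediate_window: 600

Omitted sections and keys fall back to the documented defaults; CLI flags
override file values.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .ingest import CsvDialect, MazeGeometry, ValidationError
from .report import AnalysisConfig

__all__ = ["load_config", "DEFAULT_GEOMETRY"]

DEFAULT_GEOMETRY = MazeGeometry(("A", "B", "C"), "ccw_is_left", frozenset({"centre"}))


def _build(cls, data: dict, what: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown {what} key(s) {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> tuple[MazeGeometry, CsvDialect, AnalysisConfig]:
    """Load (geometry, dialect, analysis) from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"geometry", "dialect", "analysis"}
    if unknown:
        raise ValidationError(f"unknown config section(s) {sorted(unknown)}")

    geom_raw = dict(raw.get("geometry") or {})
    if geom_raw:
        arms = geom_raw.pop("arms", None)
        if arms is None:
            raise ValidationError("geometry section requires 'arms'")
        geom = MazeGeometry(
            tuple(arms),
            geom_raw.pop("chirality", "ccw_is_left"),
            frozenset(geom_raw.pop("non_arm_zones", [])),
        )
        if geom_raw:
            raise ValidationError(f"unknown geometry key(s) {sorted(geom_raw)}")
    else:
        geom = DEFAULT_GEOMETRY

    dialect = _build(CsvDialect, dict(raw.get("dialect") or {}), "dialect")
    analysis = _build(AnalysisConfig, dict(raw.get("analysis") or {}), "analysis")
    return geom, dialect, analysis
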