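"""Reading and writing visit logs, rosters and timelines.

All tables are delimited text (comma or tab, sniffed from the header line).
Timestamps may be numeric seconds or ISO-8601 wall-clock strings; ISO values
are converted to float seconds from a per-experiment epoch at this boundary
and nowhere else.  A small column-mapping config adapts exports from
different cage-system software dialects without code changes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import (
    ROSTER_COLUMNS,
    VISIT_COLUMNS,
    ConfigError,
    ExperimentTimeline,
    ValidationError,
    validate_roster,
    validate_visits,
)

DEFAULT_MAPPING = {c: c for c in VISIT_COLUMNS}


def load_column_mapping(path: str | Path) -> dict[str, str]:
    """Load a YAML column-mapping config: canonical name -> file column."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"column mapping {path} must be a mapping")
    mapping = dict(DEFAULT_MAPPING)
    unknown = set(raw) - set(VISIT_COLUMNS)
    if unknown:
        raise ConfigError(f"unknown canonical columns in mapping: {sorted(unknown)}")
    mapping.update({k: str(v) for k, v in raw.items()})
    return mapping


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _to_seconds(series: pd.Series, epoch, what: str) -> pd.Series:
    """Convert a timestamp column to float seconds from the epoch."""
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    # treat as wall-clock ISO strings
    stamps = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = stamps.isna()
    if bad.any():
        raise ValidationError(
            f"unparseable {what} timestamps", list(np.nonzero(bad.to_numpy())[0])
        )
    ep = resolve_epoch(epoch, stamps)
    return (stamps - ep).dt.total_seconds().astype(float)


def resolve_epoch(epoch, stamps: pd.Series | None = None) -> pd.Timestamp:
    """Resolve an epoch spec (Timestamp, ISO string, or None).

    ``None`` defaults to midnight of the earliest timestamp's date, which is
    deterministic for a given file and keeps all offsets positive.
    """
    if epoch is None:
        if stamps is None or len(stamps) == 0:
            raise ConfigError("an epoch is required to convert ISO timestamps")
        return pd.Timestamp(stamps.min().date())
    return pd.Timestamp(epoch)


def read_visits(
    path: str | Path,
    mapping: dict[str, str] | str | Path | None = None,
    roster: pd.DataFrame | None = None,
    epoch=None,
) -> pd.DataFrame:
    """Read and validate a visit table.

    Parameters
    ----------
    path : file of delimited text with a header row.
    mapping : canonical->file column mapping (dict or YAML path); omitted
        canonical names default to themselves.
    roster : optional validated roster for referential-integrity checking.
    epoch : epoch for ISO timestamps (ignored for numeric seconds).

    Returns the validated table, sorted by entry time.  Malformed rows raise
    :class:`~cagecontagion.events.ValidationError` naming the offending rows.
    """
    if mapping is None:
        mapping = DEFAULT_MAPPING
    elif not isinstance(mapping, dict):
        mapping = load_column_mapping(mapping)
    raw = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, skipinitialspace=True)
    missing = [fc for fc in mapping.values() if fc not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: mapped columns absent from file: {missing}")
    df = pd.DataFrame(
        {canon: raw[filecol] for canon, filecol in mapping.items()}
    )
    if len(df):
        df["entry"] = _to_seconds(df["entry"], epoch, "entry")
        df["exit"] = _to_seconds(df["exit"], epoch, "exit")
    return validate_visits(df, roster=roster)


def write_visits(visits: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a visit table in the canonical dialect (numeric seconds).

    ``read_visits`` on the result yields a field-for-field identical table.
    """
    out = visits.loc[:, VISIT_COLUMNS].copy()
    with open(path, "w", newline="") as fh:
        out.to_csv(fh, sep=sep, index=False, float_format="%.17g")


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read and validate a roster table (animal, cage, strain, role)."""
    raw = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, skipinitialspace=True)
    missing = [c for c in ROSTER_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: roster is missing columns {missing}")
    return validate_roster(raw)


def write_roster(roster: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    roster.loc[:, ROSTER_COLUMNS].to_csv(path, sep=sep, index=False)


def read_timeline(path: str | Path) -> ExperimentTimeline:
    """Read an experiment timeline from a YAML config.

    Expected keys: ``habituation_window`` and ``baseline_window`` (each a
    two-element list), ``reintroduction_time``, and optionally
    ``contagion_window_length`` (seconds, default 1800) and ``epoch`` (ISO
    timestamp; required when the window values are ISO strings).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"timeline {path} must be a mapping")
    for key in ("habituation_window", "baseline_window", "reintroduction_time"):
        if key not in raw:
            raise ConfigError(f"timeline {path} lacks required key {key!r}")
    epoch = raw.get("epoch")

    def conv(value):
        if isinstance(value, (int, float)):
            return float(value)
        if epoch is None:
            raise ConfigError(
                f"timeline {path}: ISO timestamp {value!r} needs an 'epoch' key"
            )
        return float((pd.Timestamp(value) - pd.Timestamp(epoch)).total_seconds())

    def window(value):
        if not isinstance(value, (list, tuple)) or len(value) != 2:
            raise ConfigError(f"timeline {path}: windows must be [start, end] pairs")
        return (conv(value[0]), conv(value[1]))

    return ExperimentTimeline(
        habituation_window=window(raw["habituation_window"]),
        baseline_window=window(raw["baseline_window"]),
        reintroduction_time=conv(raw["reintroduction_time"]),
        contagion_window_length=float(raw.get("contagion_window_length", 1800.0)),
    )


def write_timeline(timeline: ExperimentTimeline, path: str | Path) -> None:
    doc = {
        "habituation_window": list(timeline.habituation_window),
        "baseline_window": list(timeline.baseline_window),
        "reintroduction_time": timeline.reintroduction_time,
        "contagion_window_length": timeline.contagion_window_length,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
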