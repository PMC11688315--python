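"""Core data model for automated home-cage visit logs.

The unit of observation is a *corner visit*: one animal inside one
instrumented drinking corner for a contiguous interval, with the licking
activity registered during that interval.  Visits are carried as a pandas
DataFrame with one row per visit (columns in :data:`VISIT_COLUMNS`); the
roster maps each animal to its cage, strain and social role
(demonstrator vs observer); the experiment timeline fixes the analysis
windows on the experiment's time axis (float seconds from a per-experiment
epoch).

Validation is total: every malformed row is reported with its positional
row number, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: canonical column order of a visit table
VISIT_COLUMNS = ["cage", "animal", "corner", "entry", "exit", "licks", "lick_duration"]

#: canonical column order of a roster table
ROSTER_COLUMNS = ["animal", "cage", "strain", "role"]

ROLE_DEMONSTRATOR = "demonstrator"
ROLE_OBSERVER = "observer"


class ValidationError(ValueError):
    """A visit table or roster violates a structural invariant.

    ``rows`` holds 0-based positional indices of offending rows where the
    failure is attributable to specific rows.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):
        self.rows = list(rows)
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


class ConfigError(ValueError):
    """A configuration file (column mapping, timeline) is unusable."""


@dataclass(frozen=True)
class VisitRecord:
    """A single corner visit.  Mostly useful for constructing fixtures;

    bulk data flows through the DataFrame representation.
    """

    cage: str
    animal: str
    corner: str
    entry: float
    exit: float
    licks: int = 0
    lick_duration: float = 0.0


@dataclass(frozen=True)
class ExperimentTimeline:
    """Named analysis windows, in seconds from the experiment epoch.

    Parameters
    ----------
    habituation_window : (start, end)
        Span of the habituation day used for the circadian comparison;
        its two equal halves are the morning and midday windows.
    baseline_window : (start, end)
        Pre-stimulus span on the test day (3 h in the reference design),
        ending shortly before the demonstrator is reintroduced.
    reintroduction_time : float
        Instant the water-deprived demonstrator re-enters the cage.
    contagion_window_length : float
        Length of the contagion analysis window (default 1800 s = 30 min).
    """

    habituation_window: tuple[float, float]
    baseline_window: tuple[float, float]
    reintroduction_time: float
    contagion_window_length: float = 1800.0

    def __post_init__(self):
        hw, bw = self.habituation_window, self.baseline_window
        if not (hw[0] < hw[1] and bw[0] < bw[1]):
            raise ValidationError("timeline windows must have start < end")
        if bw[1] > self.reintroduction_time:
            raise ValidationError(
                "baseline window must precede the reintroduction instant"
            )
        if self.contagion_window_length <= 0:
            raise ValidationError("contagion_window_length must be positive")

    @property
    def contagion_window(self) -> tuple[float, float]:
        t0 = self.reintroduction_time
        return (t0, t0 + self.contagion_window_length)

    @property
    def habituation_morning(self) -> tuple[float, float]:
        a, b = self.habituation_window
        return (a, (a + b) / 2.0)

    @property
    def habituation_midday(self) -> tuple[float, float]:
        a, b = self.habituation_window
        return ((a + b) / 2.0, b)

    def window(self, label: str) -> tuple[float, float]:
        """Resolve a window by its conventional label."""
        table = {
            "baseline": self.baseline_window,
            "contagion": self.contagion_window,
            "habituation": self.habituation_window,
            "habituation-morning": self.habituation_morning,
            "habituation-midday": self.habituation_midday,
        }
        try:
            return table[label]
        except KeyError:
            raise KeyError(f"unknown window label {label!r}; one of {sorted(table)}")


def visits_frame(records: Sequence[VisitRecord] | None = None) -> pd.DataFrame:
    """Build a canonical visit DataFrame from :class:`VisitRecord` objects."""
    if not records:
        return pd.DataFrame(
            {
                "cage": pd.Series(dtype=str),
                "animal": pd.Series(dtype=str),
                "corner": pd.Series(dtype=str),
                "entry": pd.Series(dtype=float),
                "exit": pd.Series(dtype=float),
                "licks": pd.Series(dtype=np.int64),
                "lick_duration": pd.Series(dtype=float),
            }
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    return df[VISIT_COLUMNS]


def validate_visits(visits: pd.DataFrame, roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a visit table and return it sorted by entry time.

    Checks, in order:

    * required columns present, timestamps finite;
    * ``exit > entry`` for every row;
    * licking consistency: ``licks == 0`` iff ``lick_duration == 0``
      (an inspection visit carries no licking signal), both non-negative;
    * duplicate visit identity ``(cage, corner, entry)`` — duplicates signal
      a parsing bug upstream and are an error, never deduplicated;
    * single-occupancy: within one ``(cage, corner)`` visit intervals do not
      overlap (the corner admits one animal at a time);
    * if ``roster`` is given, referential integrity of animal ids.

    Returns a copy sorted by ``(entry, cage, corner)`` with a fresh index.
    Positional row numbers in error messages refer to the *input* order.
    """
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise ConfigError(f"visit table is missing columns {missing}")
    v = visits.loc[:, VISIT_COLUMNS].copy()
    v["entry"] = pd.to_numeric(v["entry"], errors="raise").astype(float)
    v["exit"] = pd.to_numeric(v["exit"], errors="raise").astype(float)
    v["licks"] = pd.to_numeric(v["licks"], errors="raise").astype(np.int64)
    v["lick_duration"] = pd.to_numeric(v["lick_duration"], errors="raise").astype(float)

    if len(v) == 0:
        return v.reset_index(drop=True)

    if not np.isfinite(v["entry"]).all() or not np.isfinite(v["exit"]).all():
        bad = np.nonzero(~(np.isfinite(v["entry"]) & np.isfinite(v["exit"])).to_numpy())[0]
        raise ValidationError("non-finite timestamps", bad)

    bad = np.nonzero((v["exit"] <= v["entry"]).to_numpy())[0]
    if bad.size:
        raise ValidationError("exit time not after entry time", bad)

    if (v["licks"] < 0).any() or (v["lick_duration"] < 0).any():
        bad = np.nonzero(((v["licks"] < 0) | (v["lick_duration"] < 0)).to_numpy())[0]
        raise ValidationError("negative licking values", bad)
    incons = (v["licks"] == 0) != (v["lick_duration"] == 0.0)
    if incons.any():
        raise ValidationError(
            "inconsistent licking signal: licks == 0 must coincide with lick_duration == 0",
            np.nonzero(incons.to_numpy())[0],
        )

    dup = v.duplicated(subset=["cage", "corner", "entry"], keep=False)
    if dup.any():
        raise ValidationError(
            "duplicate visit identity (cage, corner, entry)", np.nonzero(dup.to_numpy())[0]
        )

    # single occupancy per corner: after sorting by entry, each visit must not
    # begin before the previous one in the same corner has ended
    for (_, _), grp in v.groupby(["cage", "corner"], sort=False):
        g = grp.sort_values("entry")
        ent = g["entry"].to_numpy()
        ext = g["exit"].to_numpy()
        overlap = ent[1:] < ext[:-1]
        if overlap.any():
            pos = np.asarray(g.index)[1:][overlap]
            raise ValidationError(
                "overlapping occupancy in one corner (corrupted log?)",
                [int(p) for p in pos],
            )

    if roster is not None:
        known = set(roster["animal"])
        unknown = ~v["animal"].isin(known)
        if unknown.any():
            raise ValidationError(
                "visit by an animal absent from the roster",
                np.nonzero(unknown.to_numpy())[0],
            )

    return v.sort_values(["entry", "cage", "corner"], kind="mergesort").reset_index(drop=True)


def validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    """Validate a roster: unique animals, one demonstrator per cage, N >= 2."""
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise ConfigError(f"roster is missing columns {missing}")
    r = roster.loc[:, ROSTER_COLUMNS].copy()
    dup = r.duplicated(subset="animal", keep=False)
    if dup.any():
        raise ValidationError("duplicate animal id in roster", np.nonzero(dup.to_numpy())[0])
    bad_role = ~r["role"].isin([ROLE_DEMONSTRATOR, ROLE_OBSERVER])
    if bad_role.any():
        raise ValidationError(
            f"role must be '{ROLE_DEMONSTRATOR}' or '{ROLE_OBSERVER}'",
            np.nonzero(bad_role.to_numpy())[0],
        )
    for cage, grp in r.groupby("cage"):
        n_dem = int((grp["role"] == ROLE_DEMONSTRATOR).sum())
        if n_dem != 1:
            raise ValidationError(
                f"cage {cage!r} has {n_dem} demonstrators, expected exactly 1"
            )
        if len(grp) < 2:
            raise ValidationError(f"cage {cage!r} has group size {len(grp)} < 2")
        strains = grp["strain"].unique()
        if len(strains) != 1:
            raise ValidationError(
                f"cage {cage!r} mixes strains {sorted(map(str, strains))}"
            )
    return r.sort_values(["cage", "role", "animal"], kind="mergesort").reset_index(drop=True)


def cage_strains(roster: pd.DataFrame) -> dict[str, str]:
    """Map cage id -> strain label (rosters never mix strains in one cage)."""
    return {str(c): str(g["strain"].iloc[0]) for c, g in roster.groupby("cage")}


def observers(roster: pd.DataFrame) -> pd.DataFrame:
    return roster[roster["role"] == ROLE_OBSERVER]


def demonstrator_of(roster: pd.DataFrame, cage: str) -> str:
    grp = roster[(roster["cage"] == cage) & (roster["role"] == ROLE_DEMONSTRATOR)]
    if len(grp) != 1:
        raise ValidationError(f"cage {cage!r} does not have exactly one demonstrator")
    return str(grp["animal"].iloc[0])
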