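"""Per-animal behavioral summaries within named time windows.

Four parameters are summarized per animal and window: total visits,
drinking visits (at least one lick), inspection visits (no licking), and
total licking time in seconds.  A visit belongs to a window iff its *entry*
time falls in the half-open interval ``[start, end)`` — attribution follows
the moment the approach decision was made, and half-open intervals make
adjacent windows partition time without double counting.

Baseline spans longer than the contagion window are made comparable by
dividing all four parameters by a time-normalization divisor (6 for a 3 h
baseline vs a 30 min contagion window).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .events import ValidationError

SUMMARY_VALUE_COLUMNS = ["total_visits", "drinking_visits", "inspection_visits", "licking_time"]

#: which licking field decides that a visit counts as drinking
DRINKING_KEYS = ("licks", "lick_duration")


def classify_visit(licks: int, lick_duration: float = 0.0, drinking_key: str = "licks") -> str:
    """Classify one visit as ``"drinking"`` or ``"inspection"``.

    The default key counts a visit as drinking iff it registered at least
    one lick; ``drinking_key="lick_duration"`` uses a positive lick contact
    time instead (the two coincide on data satisfying the licking-signal
    invariant).
    """
    if drinking_key not in DRINKING_KEYS:
        raise ValueError(f"drinking_key must be one of {DRINKING_KEYS}")
    if drinking_key == "licks":
        return "drinking" if licks >= 1 else "inspection"
    return "drinking" if lick_duration > 0 else "inspection"


def _drinking_mask(visits: pd.DataFrame, drinking_key: str) -> np.ndarray:
    if drinking_key not in DRINKING_KEYS:
        raise ValueError(f"drinking_key must be one of {DRINKING_KEYS}")
    if drinking_key == "licks":
        return (visits["licks"].to_numpy() >= 1)
    return (visits["lick_duration"].to_numpy() > 0)


def summarize_window(
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    window: tuple[float, float],
    label: str = "window",
    normalization_divisor: float = 1.0,
    drinking_key: str = "licks",
    warn_outside_span: bool = True,
) -> pd.DataFrame:
    """Summarize the four behavioral parameters per animal over one window.

    Every animal in the roster appears in the output, with an all-zero row
    when it made no visits — passive animals must be representable.  Counts
    (and licking time: the normalization applies to all four parameters) are
    divided by ``normalization_divisor``.

    Returns a DataFrame with columns ``animal, window_label, total_visits,
    drinking_visits, inspection_visits, licking_time, normalized,
    normalization_divisor``, sorted by animal id.
    """
    start, end = window
    if not end > start:
        raise ValidationError(f"window {window} must have start < end")
    if not normalization_divisor > 0:
        raise ValidationError("normalization_divisor must be positive")

    if len(visits) and warn_outside_span:
        lo, hi = visits["entry"].min(), visits["entry"].max()
        if end <= lo or start > hi:
            warnings.warn(
                f"window [{start}, {end}) lies outside the recorded span "
                f"[{lo}, {hi}]; summaries will be all zero",
                stacklevel=2,
            )

    ent = visits["entry"].to_numpy() if len(visits) else np.empty(0)
    in_win = (ent >= start) & (ent < end)
    sel = visits.iloc[np.nonzero(in_win)[0]] if len(visits) else visits

    animals = sorted(roster["animal"].astype(str))
    # visits by animals outside this roster (e.g. the demonstrator when
    # summarizing observers only) are simply not part of the summary
    sel = sel[sel["animal"].astype(str).isin(animals)]
    out = pd.DataFrame(
        {
            "animal": animals,
            "window_label": label,
            "total_visits": 0.0,
            "drinking_visits": 0.0,
            "inspection_visits": 0.0,
            "licking_time": 0.0,
        }
    ).set_index("animal")

    if len(sel):
        drink = _drinking_mask(sel, drinking_key)
        grp = sel.assign(_drink=drink).groupby(sel["animal"].astype(str))
        total = grp.size()
        drinking = grp["_drink"].sum()
        lick_time = grp["lick_duration"].sum()
        out.loc[total.index, "total_visits"] = total.astype(float)
        out.loc[drinking.index, "drinking_visits"] = drinking.astype(float)
        out["inspection_visits"] = out["total_visits"] - out["drinking_visits"]
        out.loc[lick_time.index, "licking_time"] = lick_time.astype(float)

    d = float(normalization_divisor)
    out[SUMMARY_VALUE_COLUMNS] = out[SUMMARY_VALUE_COLUMNS] / d
    out["normalized"] = d != 1.0
    out["normalization_divisor"] = d
    return out.reset_index()


def circadian_compare(
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    window_am: tuple[float, float],
    window_pm: tuple[float, float],
    drinking_key: str = "licks",
) -> pd.DataFrame:
    """Paired per-animal summaries for two equal-length, disjoint windows.

    Feeds the repeated-measures comparison of morning vs midday activity.
    Returns the concatenation of the two window summaries (labels
    ``habituation-morning`` / ``habituation-midday``), one row per animal and
    window; an animal absent from one window gets a zero row there.
    """
    if not (window_am[1] <= window_pm[0] or window_pm[1] <= window_am[0]):
        raise ValidationError("morning and midday windows must be disjoint")
    len_am = window_am[1] - window_am[0]
    len_pm = window_pm[1] - window_pm[0]
    if not np.isclose(len_am, len_pm):
        raise ValidationError("the two circadian windows must have equal length")
    am = summarize_window(
        visits, roster, window_am, "habituation-morning",
        drinking_key=drinking_key, warn_outside_span=False,
    )
    pm = summarize_window(
        visits, roster, window_pm, "habituation-midday",
        drinking_key=drinking_key, warn_outside_span=False,
    )
    return pd.concat([am, pm], ignore_index=True)


def paired_long(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, parameter: str
) -> pd.DataFrame:
    """Stack two per-animal summaries into long form for one parameter.

    Output columns: ``animal, condition, value`` with condition taken from
    each summary's ``window_label``.  Both summaries must cover the same
    animals (no imputation is performed).
    """
    if parameter not in SUMMARY_VALUE_COLUMNS:
        raise KeyError(f"parameter must be one of {SUMMARY_VALUE_COLUMNS}")
    a = summary_a[["animal", "window_label", parameter]]
    b = summary_b[["animal", "window_label", parameter]]
    if set(a["animal"]) != set(b["animal"]):
        raise ValidationError("paired summaries must cover identical animal sets")
    long = pd.concat([a, b], ignore_index=True).rename(
        columns={"window_label": "condition", parameter: "value"}
    )
    return long.sort_values(["animal", "condition"], kind="mergesort").reset_index(drop=True)
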