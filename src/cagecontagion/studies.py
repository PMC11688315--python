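"""Monte-Carlo studies over the simulator: test calibration (type-I error
under a null colony), power of the pooled strain contrast, and parameter
recovery.  These drive the package's own validation and the reproduction
script; they are ordinary library functions so that the same computations
can be re-run, seeded, from tests, scripts or notebooks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import ROLE_OBSERVER, ExperimentTimeline
from .simulate import (
    CONTROL_LIKE,
    MODEL_LIKE,
    SimulationConfig,
    StrainProfile,
    simulate_colony,
)
from .stats import UndefinedStatisticError, chi_square_2x2, rm_anova
from .windows import paired_long, summarize_window


def calibration_config() -> SimulationConfig:
    """Study design for calibration runs: 4 cages x 5 animals per strain,
    test day only (the circadian habituation block is not involved)."""
    return SimulationConfig(
        n_cages=4, group_size=5, include_habituation=False, post_reintro_span=1800.0
    )


def null_profiles(lambda0: float = CONTROL_LIKE.lambda0) -> dict[str, StrainProfile]:
    """Two pseudo-strains with identical behavior and the contagion kernel
    disabled: the simulated null of no strain difference and no contagion."""
    return {
        "null-a": StrainProfile("null-a", lambda0=lambda0, p_copy=0.0, f_fast=0.7),
        "null-b": StrainProfile("null-b", lambda0=lambda0, p_copy=0.0, f_fast=0.7),
    }


def activation_table(
    visits: pd.DataFrame, roster: pd.DataFrame, timeline: ExperimentTimeline
) -> dict[str, tuple[int, int]]:
    """Pooled activated/passive observer counts per strain.

    An observer is activated when it made >= 1 visit (entry inside the
    contagion window).  Returns ``strain -> (activated, passive)``.
    """
    summary = summarize_window(
        visits, roster, timeline.contagion_window, "contagion",
        warn_outside_span=False,
    )
    merged = summary.merge(roster, on="animal")
    obs = merged[merged["role"] == ROLE_OBSERVER]
    out = {}
    for strain, grp in obs.groupby("strain"):
        act = int((grp["total_visits"] >= 1).sum())
        out[str(strain)] = (act, len(grp) - act)
    return out


def _activation_chi2_p(visits, roster, timeline) -> float | None:
    tab = activation_table(visits, roster, timeline)
    (a, b), (c, d) = [tab[s] for s in sorted(tab)]
    try:
        return chi_square_2x2([[a, b], [c, d]]).p_value
    except UndefinedStatisticError:
        return None


def _rm_within_p(visits, roster, timeline, divisor: float) -> float | None:
    """Within-factor (baseline vs contagion) p for one strain's observers,
    on total visits, textbook df convention."""
    obs = roster[roster["role"] == ROLE_OBSERVER]
    base = summarize_window(
        visits, obs, timeline.baseline_window, "baseline",
        normalization_divisor=divisor, warn_outside_span=False,
    )
    cont = summarize_window(
        visits, obs, timeline.contagion_window, "contagion", warn_outside_span=False,
    )
    long = paired_long(base, cont, "total_visits")
    long["cage"] = long["animal"].map(obs.set_index("animal")["cage"])
    try:
        res = rm_anova(long, df_convention="residual")
    except Exception:
        return None
    within = [r for r in res if r.effect == "within"][0]
    return None if np.isnan(within.p_value) else within.p_value


def type_one_error_study(
    n_seeds: int,
    seed: int,
    alpha: float = 0.05,
    config: SimulationConfig | None = None,
) -> dict:
    """Type-I error of the pooled activation chi-square and of the
    repeated-measures (baseline vs contagion) test under the simulated null.

    Each seed simulates a full null colony (two identical pseudo-strains,
    contagion kernel off); the chi-square compares the strains' pooled
    activated-observer counts, the RM test compares baseline vs contagion
    total visits within the first pseudo-strain.  Seeds on which a test is
    undefined (degenerate tables or zero variance) are excluded from that
    test's denominator; their count is reported.
    """
    cfg = config or calibration_config()
    profiles = null_profiles()
    b0, b1 = cfg.timeline.baseline_window
    divisor = (b1 - b0) / cfg.timeline.contagion_window_length
    ss = np.random.SeedSequence(seed)
    chi_rej = chi_n = rm_rej = rm_n = 0
    for child in ss.spawn(n_seeds):
        visits, roster, tl = simulate_colony(cfg, profiles, child)
        p = _activation_chi2_p(visits, roster, tl)
        if p is not None:
            chi_n += 1
            chi_rej += p < alpha
        strain_a = roster[roster["strain"] == "null-a"]
        va = visits[visits["cage"].isin(strain_a["cage"])]
        p = _rm_within_p(va, strain_a, tl, divisor)
        if p is not None:
            rm_n += 1
            rm_rej += p < alpha
    return {
        "n_seeds": n_seeds,
        "alpha": alpha,
        "chi2_type_one_error": chi_rej / chi_n if chi_n else float("nan"),
        "chi2_n_defined": chi_n,
        "rm_type_one_error": rm_rej / rm_n if rm_n else float("nan"),
        "rm_n_defined": rm_n,
    }


def strain_contrast_study(
    n_seeds: int,
    seed: int,
    alpha: float = 0.05,
    config: SimulationConfig | None = None,
    profiles: dict[str, StrainProfile] | None = None,
) -> dict:
    """Power of the pooled activated-observer chi-square for the
    control-like vs model-like contrast, plus the mean activated-observer
    proportions per profile."""
    cfg = config or calibration_config()
    profs = profiles or {CONTROL_LIKE.label: CONTROL_LIKE, MODEL_LIKE.label: MODEL_LIKE}
    ss = np.random.SeedSequence(seed)
    rej = n_def = 0
    props: dict[str, list[float]] = {label: [] for label in profs}
    for child in ss.spawn(n_seeds):
        visits, roster, tl = simulate_colony(cfg, profs, child)
        tab = activation_table(visits, roster, tl)
        for label, (a, b) in tab.items():
            props[label].append(a / (a + b))
        p = _activation_chi2_p(visits, roster, tl)
        if p is not None:
            n_def += 1
            rej += p < alpha
    return {
        "n_seeds": n_seeds,
        "alpha": alpha,
        "rejection_rate": rej / n_def if n_def else float("nan"),
        "n_defined": n_def,
        "mean_activated_proportion": {
            label: float(np.mean(v)) for label, v in props.items()
        },
    }
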