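"""Shared fixtures: small hand-built logs and a random valid-log generator
(occupancy-respecting), used by unit and property tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cagecontagion.events import (
    ROSTER_COLUMNS,
    VISIT_COLUMNS,
    ExperimentTimeline,
    validate_visits,
)


@pytest.fixture
def timeline() -> ExperimentTimeline:
    return ExperimentTimeline(
        habituation_window=(0.0, 21600.0),
        baseline_window=(30000.0, 40800.0),
        reintroduction_time=41400.0,
        contagion_window_length=1800.0,
    )


@pytest.fixture
def roster5() -> pd.DataFrame:
    """One cage: a demonstrator and four observers."""
    return pd.DataFrame(
        {
            "animal": ["D1", "O1", "O2", "O3", "O4"],
            "cage": "C1",
            "strain": "control",
            "role": ["demonstrator"] + ["observer"] * 4,
        }
    )[ROSTER_COLUMNS]


def make_visits(rows):
    """rows: (animal, corner, entry, exit, licks, lick_duration), cage C1."""
    df = pd.DataFrame(
        [("C1",) + tuple(r) for r in rows], columns=VISIT_COLUMNS
    )
    return validate_visits(df)


def random_valid_log(
    rng: np.random.Generator,
    animals=("D1", "O1", "O2", "O3"),
    corners=("K1", "K2"),
    span=600.0,
    mean_gap=6.0,
    cage="C1",
) -> pd.DataFrame:
    """A random occupancy-respecting visit log.

    Gaps between consecutive same-corner visits are exponential with a mean
    chosen to produce many near-threshold latencies, so the copied-visit
    boundary gets exercised.
    """
    rows = []
    for corner in corners:
        t = rng.uniform(0, 20)
        while t < span:
            dur = rng.uniform(1.0, 10.0)
            if t + dur > span + 60:
                break
            animal = animals[rng.integers(len(animals))]
            if rng.uniform() < 0.5:
                lick_dur = rng.uniform(0.5, min(dur, 15.0))
                licks = max(1, int(lick_dur * 6))
            else:
                lick_dur, licks = 0.0, 0
            rows.append((cage, animal, corner, t, t + dur, licks, lick_dur))
            t = t + dur + rng.exponential(mean_gap)
    df = pd.DataFrame(rows, columns=VISIT_COLUMNS)
    # shuffle rows: detection must not depend on input order
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    return validate_visits(df)
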