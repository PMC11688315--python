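"""Stochastic colony simulator.

Emulates the structure of the behavioral-contagion experiment: a group of
animals in an automated cage with two instrumented drinking corners, a
water-deprived demonstrator producing a dense, decaying train of drinking
visits from the instant of its reintroduction, observers with a low
baseline visit rate, and a one-step triggered contagion mechanism — after
every completed visit, each other animal independently schedules a
follow-up visit to the same corner with probability ``p_copy`` and a random
latency.  Cascades emerge because copy visits can themselves be copied.

Corner occupancy is enforced: one animal per corner at a time, and one
corner per animal at a time.  A scheduled entry during occupancy is delayed
until both the corner and the animal are free, which can push a copy's
measured latency past the detection threshold — measured contagion is
realistically attenuated relative to the generative ``p_copy``.

The default time axis places the habituation circadian windows on day 0
(09:00-15:00) and the test day on day 1: baseline 08:50-11:50, demonstrator
reintroduction at 12:01, contagion window the following 30 min.  Everything
is reproducible: ``(config, profile, seed)`` determines the event stream
bit for bit.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contagion import DEFAULT_LATENCY_THRESHOLD, detect_copied_visits
from .events import (
    ROLE_DEMONSTRATOR,
    ROLE_OBSERVER,
    ROSTER_COLUMNS,
    VISIT_COLUMNS,
    ExperimentTimeline,
    validate_visits,
)

_DAY = 86400.0

DEFAULT_TIMELINE = ExperimentTimeline(
    habituation_window=(9 * 3600.0, 15 * 3600.0),            # day 0, 09:00-15:00
    baseline_window=(_DAY + 31800.0, _DAY + 42600.0),        # day 1, 08:50-11:50
    reintroduction_time=_DAY + 43260.0,                      # day 1, 12:01
    contagion_window_length=1800.0,
)


@dataclass(frozen=True)
class StrainProfile:
    """Behavioral parameters that differ between strains.

    ``lambda0`` is the observer baseline visit rate (visits/hour),
    ``p_copy`` the per-witnessed-visit copy probability per observer, and
    ``f_fast`` the fraction of copy latencies drawn from the short uniform
    component of the latency mixture.
    """

    label: str
    lambda0: float
    p_copy: float
    f_fast: float

    def __post_init__(self):
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be >= 0")
        if not 0 <= self.p_copy <= 1:
            raise ValueError("p_copy must lie in [0, 1]")
        if not 0 <= self.f_fast <= 1:
            raise ValueError("f_fast must lie in [0, 1]")


#: preset emulating a socially responsive control cohort
CONTROL_LIKE = StrainProfile(label="control-like", lambda0=1.2, p_copy=0.6, f_fast=0.7)
#: preset emulating a contagion-attenuated model cohort
MODEL_LIKE = StrainProfile(label="model-like", lambda0=0.8, p_copy=0.05, f_fast=0.5)

PROFILES = {p.label: p for p in (CONTROL_LIKE, MODEL_LIKE)}


@dataclass(frozen=True)
class SimulationConfig:
    """Structural and kinetic parameters shared by all simulated cages.

    Rates are per hour, times in seconds.  The demonstrator's bout train is
    an inhomogeneous Poisson process with rate
    ``demo_rate0 * exp(-(t - t_reintro) / demo_decay_tau)`` from the moment
    of reintroduction.  Copy latencies are a mixture: with probability
    ``f_fast`` (from the strain profile) uniform on ``(0, fast_latency_max)``,
    otherwise exponential with mean ``slow_latency_mean`` (truncated at the
    end of the simulated span).  A single drinking bout cannot outlast the
    door-open time.
    """

    n_cages: int = 4
    group_size: int = 5
    n_corners: int = 2
    demo_rate0: float = 60.0           # visits/h at reintroduction
    demo_decay_tau: float = 1200.0     # s
    fast_latency_max: float = 3.0      # s
    slow_latency_mean: float = 60.0    # s
    visit_duration_mean: float = 8.0   # s
    visit_duration_jitter: float = 3.0 # s (sd of the truncated normal)
    visit_duration_min: float = 1.0    # s
    door_open_time: float = 15.0       # s, caps a single bout's licking
    refractory_period: float = 300.0   # s: a just-visited animal cannot be re-triggered
    p_drink_observer: float = 0.5
    p_drink_demonstrator: float = 0.9
    lick_rate: float = 6.0             # licks/s while drinking
    post_reintro_span: float = 3600.0  # s simulated past reintroduction
    include_habituation: bool = True   # simulate the circadian habituation day
    timeline: ExperimentTimeline = DEFAULT_TIMELINE
    max_events_per_cage: int = 200_000

    def __post_init__(self):
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.n_corners < 1:
            raise ValueError("n_corners must be >= 1")
        for name in ("demo_rate0", "demo_decay_tau", "fast_latency_max",
                     "slow_latency_mean", "visit_duration_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class OccupancyOverflowError(RuntimeError):
    """The scheduled-event queue exceeded its safety bound: the configured
    rates are too high for the corners to ever drain."""


def _cage_roster(cage: str, strain: str, group_size: int) -> pd.DataFrame:
    animals = [f"{cage}-D1"] + [f"{cage}-O{i}" for i in range(1, group_size)]
    roles = [ROLE_DEMONSTRATOR] + [ROLE_OBSERVER] * (group_size - 1)
    return pd.DataFrame(
        {"animal": animals, "cage": cage, "strain": strain, "role": roles}
    )[ROSTER_COLUMNS]


def _poisson_times(rng: np.random.Generator, rate_per_h: float,
                   start: float, end: float) -> np.ndarray:
    """Homogeneous Poisson event times on [start, end)."""
    if rate_per_h <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate_per_h * (end - start) / 3600.0)
    return np.sort(rng.uniform(start, end, size=n))


def _demo_bout_times(rng: np.random.Generator, cfg: SimulationConfig,
                     t0: float, end: float) -> np.ndarray:
    """Decaying-rate bout times after reintroduction, by thinning."""
    if cfg.demo_rate0 <= 0 or end <= t0:
        return np.empty(0)
    cand = _poisson_times(rng, cfg.demo_rate0, t0, end)
    keep = rng.uniform(size=cand.size) < np.exp(-(cand - t0) / cfg.demo_decay_tau)
    return cand[keep]


def simulate_cage(
    config: SimulationConfig,
    profile: StrainProfile,
    seed: int | np.random.SeedSequence,
    cage: str = "C1",
) -> tuple[pd.DataFrame, pd.DataFrame, ExperimentTimeline]:
    """Simulate one cage and return ``(visits, roster, timeline)``.

    The visit table passes all validators (single occupancy guaranteed);
    identical ``(config, profile, seed)`` yield identical tables.
    """
    rng = np.random.default_rng(seed)
    tl = config.timeline
    roster = _cage_roster(cage, profile.label, config.group_size)
    demonstrator = roster.loc[roster["role"] == ROLE_DEMONSTRATOR, "animal"].iloc[0]
    obs_ids = list(roster.loc[roster["role"] == ROLE_OBSERVER, "animal"])
    corners = [f"K{i}" for i in range(1, config.n_corners + 1)]

    hab0, hab1 = tl.habituation_window
    base0 = tl.baseline_window[0]
    t_re = tl.reintroduction_time
    span_end = t_re + config.post_reintro_span

    # presence spans: observers throughout; the demonstrator only during
    # habituation (it is removed for deprivation) and after reintroduction
    hab = [(hab0, hab1)] if config.include_habituation else []
    spans = {a: hab + [(base0, span_end)] for a in obs_ids}
    spans[demonstrator] = hab + [(t_re, span_end)]

    # ---- seed the event heap with each animal's endogenous visit times ----
    # heap entries: (time, seq, animal, corner, is_copy_intent)
    heap: list[tuple[float, int, str, str, bool]] = []
    seq = 0
    for a in obs_ids + [demonstrator]:
        times = [
            _poisson_times(rng, profile.lambda0, s, e)
            for (s, e) in spans[a]
            if a != demonstrator or e <= hab1  # demonstrator baseline only in habituation
        ]
        for t in np.concatenate(times) if times else ():
            heapq.heappush(heap, (float(t), seq, a, corners[rng.integers(len(corners))], False))
            seq += 1
    for t in _demo_bout_times(rng, config, t_re, span_end):
        heapq.heappush(
            heap, (float(t), seq, demonstrator, corners[rng.integers(len(corners))], False)
        )
        seq += 1

    def present(a: str, t: float) -> bool:
        return any(s <= t < e for (s, e) in spans[a])

    corner_free = {c: -np.inf for c in corners}
    animal_free = {a: -np.inf for a in roster["animal"]}
    # an animal carries at most one pending copy intent at a time; being
    # re-triggered while already intending to visit does not create a
    # second visit (this keeps the supercritical regime physically bounded
    # by corner throughput instead of an unbounded intent backlog)
    has_intent = {a: False for a in roster["animal"]}
    rows: list[tuple] = []
    n_processed = 0

    while heap:
        t, _, animal, corner, is_intent = heapq.heappop(heap)
        n_processed += 1
        if n_processed > config.max_events_per_cage:
            raise OccupancyOverflowError(
                f"cage {cage}: more than {config.max_events_per_cage} scheduled "
                "events; rates are too high for the corners to drain"
            )
        if t >= span_end or not present(animal, t):
            if is_intent:
                has_intent[animal] = False
            continue
        t_ok = max(t, corner_free[corner], animal_free[animal])
        if t_ok > t:
            if t_ok < span_end:
                heapq.heappush(heap, (float(t_ok), seq, animal, corner, is_intent))
                seq += 1
            elif is_intent:
                has_intent[animal] = False
            continue
        if is_intent:
            has_intent[animal] = False

        dur = max(
            config.visit_duration_min,
            rng.normal(config.visit_duration_mean, config.visit_duration_jitter),
        )
        exit_t = t + dur
        p_drink = (
            config.p_drink_demonstrator if animal == demonstrator
            else config.p_drink_observer
        )
        if rng.uniform() < p_drink:
            lick_time = rng.uniform(0.3, 0.9) * min(dur, config.door_open_time)
            licks = max(1, int(round(lick_time * config.lick_rate)))
        else:
            lick_time, licks = 0.0, 0
        rows.append((cage, animal, corner, float(t), float(exit_t), licks, float(lick_time)))
        corner_free[corner] = exit_t
        animal_free[animal] = exit_t

        # one-step triggering: every completed visit may recruit followers.
        # an animal is triggerable only when free and past its refractory
        # period (exit_t >= its last exit + refractory), not already
        # intending a visit, and present in the cage
        if profile.p_copy > 0:
            for other in roster["animal"]:
                if other == animal or has_intent[other] or not present(other, exit_t):
                    continue
                if exit_t < animal_free[other] + config.refractory_period:
                    continue
                if rng.uniform() >= profile.p_copy:
                    continue
                if rng.uniform() < profile.f_fast:
                    lat = rng.uniform(0.0, config.fast_latency_max)
                else:
                    lat = rng.exponential(config.slow_latency_mean)
                t_copy = exit_t + lat
                if t_copy < span_end:  # truncated at the simulated span's end
                    has_intent[other] = True
                    heapq.heappush(heap, (float(t_copy), seq, other, corner, True))
                    seq += 1

    visits = pd.DataFrame(rows, columns=VISIT_COLUMNS)
    visits = validate_visits(visits, roster=roster)
    return visits, roster, tl


def simulate_colony(
    config: SimulationConfig,
    profiles: dict[str, StrainProfile],
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame, ExperimentTimeline]:
    """Simulate ``config.n_cages`` cages per strain profile.

    Returns the concatenated visit table, the combined roster, and the
    (shared) timeline.  Cage ids are ``"<strain>-G<i>"``.
    """
    ss = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(profiles) * config.n_cages)
    all_visits, all_rosters = [], []
    k = 0
    for label in sorted(profiles):
        prof = profiles[label]
        for i in range(1, config.n_cages + 1):
            v, r, tl = simulate_cage(config, prof, children[k], cage=f"{label}-G{i}")
            all_visits.append(v)
            all_rosters.append(r)
            k += 1
    visits = pd.concat(all_visits, ignore_index=True)
    roster = pd.concat(all_rosters, ignore_index=True)
    return validate_visits(visits, roster=roster), roster, config.timeline


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryResult:
    """Moment-based estimates of the generative parameters across seeds.

    The copy probability is estimated by the pooled ratio
    ``sum(copied) / (sum(opportunities) * q)`` across seeds rather than by
    averaging per-seed ratios: a successful trigger makes the follower
    refractory and truncates that seed's opportunity count, so per-seed
    ratios are upward biased under this adaptive stopping while the pooled
    ratio is not.  Its standard error is the standard ratio-estimator SE.
    """

    lambda0_true: float | None
    p_copy_true: float | None
    q_detectable: float
    lambda0_estimates: np.ndarray = field(repr=False)
    n_copied: np.ndarray = field(repr=False)
    n_opportunities: np.ndarray = field(repr=False)

    @property
    def n_seeds(self) -> int:
        return len(self.lambda0_estimates)

    @property
    def lambda0_mean(self) -> float:
        return float(np.mean(self.lambda0_estimates))

    @property
    def lambda0_se(self) -> float:
        e = self.lambda0_estimates
        return float(np.std(e, ddof=1) / np.sqrt(len(e)))

    @property
    def p_copy_mean(self) -> float:
        opp = float(self.n_opportunities.sum())
        if opp == 0 or self.q_detectable <= 0:
            return float("nan")
        return float(self.n_copied.sum() / (opp * self.q_detectable))

    @property
    def p_copy_se(self) -> float:
        d, o = self.n_copied.astype(float), self.n_opportunities.astype(float)
        n = len(d)
        ratio = d.sum() / o.sum()
        resid = d - ratio * o
        return float(
            np.sqrt(np.sum(resid**2) / (n * (n - 1))) / o.mean() / self.q_detectable
        )

    def bias(self) -> dict[str, float | None]:
        return {
            "lambda0": None if self.lambda0_true is None
            else self.lambda0_mean - self.lambda0_true,
            "p_copy": None if self.p_copy_true is None
            else self.p_copy_mean - self.p_copy_true,
        }


def detectable_latency_fraction(
    config: SimulationConfig, profile: StrainProfile,
    latency_threshold: float = DEFAULT_LATENCY_THRESHOLD,
) -> float:
    """Probability that a generated copy latency falls under the detection
    threshold: the mixture mass below ``latency_threshold``."""
    u = min(1.0, latency_threshold / config.fast_latency_max) if config.fast_latency_max > 0 else 1.0
    e = 1.0 - np.exp(-latency_threshold / config.slow_latency_mean)
    return float(profile.f_fast * u + (1.0 - profile.f_fast) * e)


def estimate_from_log(
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    timeline: ExperimentTimeline,
    q_detectable: float,
    latency_threshold: float = DEFAULT_LATENCY_THRESHOLD,
    refractory_period: float = 300.0,
) -> tuple[float, int, int]:
    """Per-log recovery counts: ``(lambda0_hat, n_copied, n_opportunities)``.

    ``lambda0_hat``: mean observer visit count in the baseline window per
    hour (unbiased when no other animal is present at baseline to trigger
    copies, as in the dyadic recovery design where the demonstrator is out
    of the cage).  ``n_copied``: detected copied visits in the contagion
    window; ``n_opportunities``: *triggerable* copy opportunities — their
    pooled ratio across seeds, divided by the detectable-latency fraction
    ``q_detectable``, estimates the copy probability (see
    :class:`RecoveryResult`).
    Both numerator and denominator are restricted to observers as
    followers — the same convention the follower metric uses — which keeps
    the demonstrator's dense endogenous bout train (whose queued re-entries
    often land within the latency threshold of an observer's exit by
    co-timing alone) out of the proxy.  A group mate counts as a
    triggerable opportunity for a visit ending at ``e`` when its own most
    recent exit lies at least ``refractory_period`` seconds before ``e``
    (or it has not visited yet).
    """
    b0, b1 = timeline.baseline_window
    hours = (b1 - b0) / 3600.0
    obs = set(roster.loc[roster["role"] == ROLE_OBSERVER, "animal"])
    ent = visits["entry"].to_numpy()
    in_base = (ent >= b0) & (ent < b1)
    n_base = int((visits["animal"].isin(obs).to_numpy() & in_base).sum())
    lam_hat = n_base / (len(obs) * hours)

    w = timeline.contagion_window
    in_win = (ent >= w[0]) & (ent < w[1])
    opp = 0
    for cage, cage_roster in roster.groupby("cage"):
        cv = visits[(visits["cage"] == cage)]
        exits_by_animal = {
            a: np.sort(g["exit"].to_numpy()) for a, g in cv.groupby("animal")
        }
        sel = cv[(cv["entry"].to_numpy() >= w[0]) & (cv["entry"].to_numpy() < w[1])]
        targets = list(cage_roster.loc[cage_roster["role"] == ROLE_OBSERVER, "animal"])
        for visitor, e in zip(sel["animal"].to_numpy(), sel["exit"].to_numpy()):
            for other in targets:
                if other == visitor:
                    continue
                ex = exits_by_animal.get(other)
                if ex is None or len(ex) == 0:
                    opp += 1
                    continue
                i = np.searchsorted(ex, e, side="right")
                if i == 0 or ex[i - 1] <= e - refractory_period:
                    opp += 1
    copied = detect_copied_visits(visits, w, latency_threshold)
    copied = copied[copied["follower"].isin(obs)]
    return lam_hat, int(len(copied)), int(opp)


def recovery_config() -> SimulationConfig:
    """Default design of the parameter-recovery study: dyads.

    With larger groups and high copy probabilities the one-step triggered
    process becomes supercritical (branching factor ``p_copy * (N - 1)``)
    and corner occupancy throttles the cascade, saturating the copied-visit
    fraction; in a dyad the branching factor equals ``p_copy`` and the
    mechanism stays identifiable over the whole ``[0, 1]`` range.
    """
    return SimulationConfig(n_cages=1, group_size=2, include_habituation=False)


def recover_parameters(
    config: SimulationConfig,
    profile: StrainProfile,
    n_seeds: int,
    seed: int | np.random.SeedSequence,
    latency_threshold: float = DEFAULT_LATENCY_THRESHOLD,
) -> RecoveryResult:
    """Simulate ``n_seeds`` independent cages and estimate the generative
    parameters from each log.  Identical seeds give identical estimates."""
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    ss = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    q = detectable_latency_fraction(config, profile, latency_threshold)
    lam, nc, no = [], [], []
    for child in ss.spawn(n_seeds):
        visits, roster, tl = simulate_cage(config, profile, child)
        lh, d, opp = estimate_from_log(
            visits, roster, tl, q, latency_threshold,
            refractory_period=config.refractory_period,
        )
        lam.append(lh)
        nc.append(d)
        no.append(opp)
    if sum(no) == 0:
        raise ValueError("no copy opportunities in any seed: p_copy estimator undefined")
    return RecoveryResult(
        lambda0_true=profile.lambda0,
        p_copy_true=profile.p_copy,
        q_detectable=q,
        lambda0_estimates=np.asarray(lam, dtype=float),
        n_copied=np.asarray(nc, dtype=np.int64),
        n_opportunities=np.asarray(no, dtype=np.int64),
    )
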