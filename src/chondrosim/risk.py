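"""Monte Carlo risk analysis: ensembles, hitting times, reliability.

A trajectory simulates one subject's daily loading history through a
:class:`~chondrosim.activity.LoadingSchedule` and records the tissue
state and health each day.  An ensemble of independently seeded
trajectories approximates the distribution of health histories; from it
we extract per-day confidence bands and the distribution of
osteoarthritis-onset hitting times — the first day each realization's
health drops below zero, counted from the lifestyle-switch day.

The module also provides the generic structural-reliability estimate of
failure probability from samples of a load and a resistance
distribution: the probability that the load exceeds the resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import LoadingSchedule, sample_day
from .dynamics import TissueParameters, TissueState, step
from .mechanics import HealthSpec, OsmoticParameters, equilibrium_strain

__all__ = [
    "Trajectory",
    "Ensemble",
    "HittingTimeSummary",
    "run_trajectory",
    "run_ensemble",
    "ensemble_band",
    "hitting_times",
    "failure_probability",
]

TRAJECTORY_COLUMNS = (
    "day", "stress", "frequency", "strain", "activity",
    "chondrocytes", "aggrecan", "collagen", "health",
)


@dataclass(frozen=True)
class Trajectory:
    """Per-day record of one simulated loading history.

    ``frame`` holds one row per simulated day with the day's sampled
    loading, the equilibrium strain and activity level it induced, the
    start-of-day densities and the start-of-day health.  Row ``t``
    therefore shows the state *before* the day-``t`` update, so row 0 is
    the initial condition.
    """

    frame: pd.DataFrame
    seed: int
    label: str = ""
    final_state: TissueState | None = field(default=None, compare=False)

    @property
    def health(self) -> np.ndarray:
        return self.frame["health"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class Ensemble:
    """Independently seeded trajectories under one schedule."""

    trajectories: tuple[Trajectory, ...]
    base_seed: int
    schedule: LoadingSchedule

    @property
    def n_realizations(self) -> int:
        return len(self.trajectories)

    def health_matrix(self) -> np.ndarray:
        """(n_realizations, horizon) array of per-day health values."""
        return np.vstack([t.health for t in self.trajectories])


@dataclass(frozen=True)
class HittingTimeSummary:
    """Censoring-aware first-passage statistics in weeks.

    ``times_weeks`` holds one entry per realization: the first-crossing
    time in weeks after the origin day, or NaN where the trajectory
    never crossed within the horizon (censored).  Mean and sd are over
    uncensored realizations only; ``mean_weeks``/``sd_weeks`` are NaN
    when everything is censored.
    """

    times_weeks: np.ndarray
    censored: np.ndarray
    mean_weeks: float
    sd_weeks: float
    censored_count: int
    n: int

    @property
    def uncensored_times(self) -> np.ndarray:
        return self.times_weeks[~self.censored]


def run_trajectory(
    schedule: LoadingSchedule,
    initial: TissueState,
    params: TissueParameters | None = None,
    osmo: OsmoticParameters | None = None,
    spec: HealthSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> Trajectory:
    """Simulate one realization of a loading schedule day by day.

    Each day: sample (stress, frequency) from the active profile, record
    the start-of-day state and health, then advance the tissue.
    Deterministic given ``seed``.
    """
    if params is None:
        params = TissueParameters()
    if osmo is None:
        osmo = OsmoticParameters()
    if spec is None:
        spec = HealthSpec()
    rng = np.random.default_rng(seed)
    horizon = schedule.total_days
    rec = np.empty((horizon, len(TRAJECTORY_COLUMNS)))
    state = initial
    threshold_strain = spec.strain_threshold
    for t in range(horizon):
        profile = schedule.profile_at(t)
        try:
            stress, freq = sample_day(profile, rng)
            strain = equilibrium_strain(state.aggrecan, stress, osmo)
            health = threshold_strain - equilibrium_strain(
                state.aggrecan, spec.test_stress, osmo
            )
            rec[t] = (
                t, stress, freq, strain, strain * freq,
                state.chondrocytes, state.aggrecan, state.collagen, health,
            )
            state = step(state, stress, freq, params, osmo)
        except Exception as exc:
            raise RuntimeError(f"trajectory failed at day {t}: {exc}") from exc
    frame = pd.DataFrame(rec, columns=list(TRAJECTORY_COLUMNS))
    frame["day"] = frame["day"].astype(int)
    seed_int = seed if isinstance(seed, int) else -1
    return Trajectory(
        frame=frame, seed=seed_int, label=schedule.label, final_state=state
    )


def run_ensemble(
    schedule: LoadingSchedule,
    params: TissueParameters | None = None,
    osmo: OsmoticParameters | None = None,
    spec: HealthSpec | None = None,
    n_realizations: int = 500,
    base_seed: int = 0,
    initial: TissueState | None = None,
) -> Ensemble:
    """Simulate independent trajectories with seeds spawned from base_seed.

    Per-realization random streams come from
    ``numpy.random.SeedSequence(base_seed).spawn(n)``, so they are
    distinct, reproducible, and independent of execution order.  All
    realizations share the same initial state.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if params is None:
        params = TissueParameters()
    if initial is None:
        initial = TissueState(
            chondrocytes=params.healthy_cell_density,
            aggrecan=100.0,
            collagen=params.col_healthy,
        )
    children = np.random.SeedSequence(base_seed).spawn(n_realizations)
    trajectories = []
    for i, child in enumerate(children):
        traj = run_trajectory(schedule, initial, params, osmo, spec, seed=child)
        object.__setattr__(traj, "seed", i)
        trajectories.append(traj)
    return Ensemble(
        trajectories=tuple(trajectories), base_seed=base_seed, schedule=schedule
    )


def ensemble_band(
    ensemble: Ensemble, level: float = 0.95, method: str = "percentile"
) -> pd.DataFrame:
    """Per-day ensemble mean health with a confidence band.

    ``method="percentile"`` (default) gives the empirical
    ``(1 - level)/2`` and ``(1 + level)/2`` percentiles across
    realizations — the band containing ``level`` of individual
    trajectories.  ``method="mean_se"`` instead gives the normal-theory
    confidence interval of the ensemble mean.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    h = ensemble.health_matrix()
    mean = h.mean(axis=0)
    if method == "percentile":
        lo = np.percentile(h, 100.0 * (1.0 - level) / 2.0, axis=0)
        hi = np.percentile(h, 100.0 * (1.0 + level) / 2.0, axis=0)
    elif method == "mean_se":
        z = float(-_norm_ppf((1.0 - level) / 2.0))
        se = h.std(axis=0, ddof=1) / math.sqrt(h.shape[0]) if h.shape[0] > 1 else 0.0
        lo, hi = mean - z * se, mean + z * se
    else:
        raise ValueError(f"unknown band method {method!r}")
    return pd.DataFrame(
        {"day": np.arange(h.shape[1]), "mean": mean, "lower": lo, "upper": hi}
    )


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return norm.ppf(q)


def hitting_times(
    ensemble: Ensemble, threshold: float = 0.0, origin_day: int = 0
) -> HittingTimeSummary:
    """First-passage times of health below a threshold, in weeks.

    For each realization, the first day at or after ``origin_day``
    (typically the lifestyle-switch day) on which health is strictly
    below ``threshold``, minus the origin, converted to weeks.
    Realizations that never cross within the horizon are censored and
    excluded from the mean and standard deviation.
    """
    h = ensemble.health_matrix()
    horizon = h.shape[1]
    if not 0 <= origin_day < horizon:
        raise ValueError(f"origin_day {origin_day} outside horizon {horizon}")
    post = h[:, origin_day:] < threshold
    first = post.argmax(axis=1)
    crossed = post.any(axis=1)
    times = np.where(crossed, first / 7.0, np.nan)
    censored = ~crossed
    n_unc = int(crossed.sum())
    if n_unc > 0:
        mean = float(np.nanmean(times))
        sd = float(np.nanstd(times, ddof=1)) if n_unc > 1 else 0.0
    else:
        mean = math.nan
        sd = math.nan
    return HittingTimeSummary(
        times_weeks=times,
        censored=censored,
        mean_weeks=mean,
        sd_weeks=sd,
        censored_count=int(censored.sum()),
        n=h.shape[0],
    )


def failure_probability(
    load_samples, resistance_samples, mode: str = "cross"
) -> float:
    """Monte Carlo failure probability P(load > resistance).

    ``mode="cross"`` treats load and resistance as independent and
    counts all cross pairs (computed by sorting, equivalent to the
    exhaustive pairwise count); ``mode="paired"`` compares draws
    elementwise, for pre-coupled samples.
    """
    load = np.asarray(load_samples, dtype=float)
    resistance = np.asarray(resistance_samples, dtype=float)
    if load.size == 0 or resistance.size == 0:
        raise ValueError("load and resistance samples must be non-empty")
    if mode == "cross":
        r_sorted = np.sort(resistance)
        # for each load, count resistances strictly below it
        below = np.searchsorted(r_sorted, load, side="left")
        return float(below.sum()) / (load.size * resistance.size)
    if mode == "paired":
        if load.size != resistance.size:
            raise ValueError("paired mode requires equal sample sizes")
        return float(np.mean(load > resistance))
    raise ValueError(f"unknown mode {mode!r}")
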