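"""Daily damage/repair dynamics of the cartilage matrix constituents.

The tissue is summarised by three spatially averaged densities: the
chondrocyte number density ``n`` (cells/mL), the aggrecan mass density
``a`` (mg/mL) and the type-II collagen mass density ``c`` (mg/mL).  Each
simulated day the tissue consolidates to its equilibrium strain under
the day's stress, the scalar activity level ``A = strain * frequency``
is formed, and the three densities are updated synchronously:

* chondrocytes proliferate logistically toward a healthy density and
  die in proportion to a sigmoid damage function of activity;
* aggrecan is synthesised per cell at an activity-stimulated rate and
  lost faster as the retaining collagen network depletes;
* collagen is synthesised per cell and lost by baseline proteolysis
  plus load-dependent mechanical damage.

The damage function is a shifted logistic sigmoid: exactly 0 at zero
activity, saturating at exactly 1 for vigorous activity, with its rise
centred on a shared activity threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .mechanics import OsmoticParameters, equilibrium_strain

__all__ = [
    "TissueState",
    "TissueParameters",
    "SteadyStateError",
    "daily_activity",
    "damage_fraction",
    "synthesis_rate",
    "step",
    "steady_state",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TissueState:
    """Densities of the three matrix constituents on a given day."""

    chondrocytes: float  # cells/mL
    aggrecan: float  # mg/mL
    collagen: float  # mg/mL
    day: int = 0

    def __post_init__(self) -> None:
        for name in ("chondrocytes", "aggrecan", "collagen"):
            if getattr(self, name) < 0:
                raise ValueError(f"TissueState.{name} must be non-negative")
        if self.day < 0:
            raise ValueError("TissueState.day must be non-negative")


@dataclass(frozen=True)
class TissueParameters:
    """Rate and threshold constants of the damage/repair model.

    Defaults are the published parameter set for a susceptible subject.
    Synthesis rates are per chondrocyte per day; loss rates are
    fractional per day; the activity threshold is in Hz (strain fraction
    times loading frequency) and the sigmoid steepnesses in seconds so
    that steepness times activity is dimensionless.
    """

    prolif_rate: float = 0.002  # 1/day, max chondrocyte proliferation
    healthy_cell_density: float = 1.0e8  # cells/mL
    cell_loss_max: float = 0.01  # 1/day, max fraction killed per day
    agg_synth_min: float = 1.1e-8  # mg/cell/day at zero activity
    agg_synth_max: float = 1.65e-8  # mg/cell/day at high activity
    agg_loss_base: float = 0.01  # 1/day
    agg_loss_extra: float = 0.005  # 1/day, added as collagen depletes
    col_synth_min: float = 1.1e-8  # mg/cell/day
    col_synth_max: float = 1.65e-8  # mg/cell/day
    col_healthy: float = 170.0  # mg/mL baseline collagen content
    col_loss_base: float = 0.006  # 1/day proteolytic turnover
    col_damage_max: float = 0.01  # 1/day max mechanical damage
    activity_threshold: float = 0.09  # Hz; 0.30 strain x 0.3 Hz
    sigmoid_cell: float = 50.0  # s, chondrocyte damage steepness
    sigmoid_col: float = 100.0  # s, collagen damage steepness

    def __post_init__(self) -> None:
        # Rates may be zeroed (useful for reduced models); structural
        # constants must be strictly positive.
        for name in (
            "healthy_cell_density", "col_healthy", "activity_threshold",
            "sigmoid_cell", "sigmoid_col",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"TissueParameters.{name} must be strictly positive")
        for name in (
            "prolif_rate", "cell_loss_max", "agg_synth_min", "agg_synth_max",
            "agg_loss_base", "agg_loss_extra", "col_synth_min", "col_synth_max",
            "col_loss_base", "col_damage_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"TissueParameters.{name} must be non-negative")
        if self.agg_synth_max < self.agg_synth_min:
            raise ValueError("agg_synth_max must be >= agg_synth_min")
        if self.col_synth_max < self.col_synth_min:
            raise ValueError("col_synth_max must be >= col_synth_min")


class SteadyStateError(RuntimeError):
    """Steady-state iteration failed to converge; carries the last state."""

    def __init__(self, message: str, last_state: TissueState):
        super().__init__(message)
        self.last_state = last_state


def _exp(x: float) -> float:
    """math.exp saturating to +inf rather than raising OverflowError."""
    return math.exp(x) if x < 709.0 else math.inf


def daily_activity(strain: float, frequency: float) -> float:
    """Daily activity level A = strain * frequency (Hz).

    A scalar rating of how vigorous the day's loading was from the
    cartilage's viewpoint: the consolidation strain it induced times the
    frequency with which it was applied.
    """
    if not 0.0 <= strain < 1.0:
        raise ValueError(f"strain must lie in [0, 1), got {strain}")
    if frequency < 0:
        raise ValueError(f"frequency must be non-negative, got {frequency}")
    return strain * frequency


def damage_fraction(activity: float, steepness: float, threshold: float) -> float:
    """Shifted sigmoid damage rating in [0, 1).

    D(A) = (1 + e^{-mu*A0}) / (1 + e^{-mu*(A - A0)})
         - (1 + e^{-mu*A0}) / (1 + e^{mu*A0})

    The shift makes D(0) = 0 exactly, and the numerator is chosen so the
    supremum as A -> infinity is exactly 1.  ``steepness`` (mu, in s)
    sets how suddenly damage turns on around the ``threshold`` (A0, Hz).
    """
    if activity < 0:
        raise ValueError(f"activity must be non-negative, got {activity}")
    if not steepness > 0:
        raise ValueError(f"steepness must be strictly positive, got {steepness}")
    if not threshold > 0:
        raise ValueError(f"threshold must be strictly positive, got {threshold}")
    k = 1.0 + _exp(-steepness * threshold)
    # Both terms share the k/(1+exp(.)) form so that D(0) cancels to 0.0
    # bit-exactly; _exp saturates to +inf instead of overflowing.
    return k / (1.0 + _exp(-steepness * (activity - threshold))) \
        - k / (1.0 + _exp(steepness * threshold))


def synthesis_rate(
    activity: float, rate_min: float, rate_max: float, threshold: float
) -> float:
    """Activity-stimulated synthesis rate per chondrocyte (mg/cell/day).

    Interpolates exponentially between the resting rate ``rate_min`` at
    zero activity and the saturated rate ``rate_max``:

    R(A) = rate_min * e^{-A/A0} + rate_max * (1 - e^{-A/A0})
    """
    if activity < 0:
        raise ValueError(f"activity must be non-negative, got {activity}")
    if not 0 <= rate_min <= rate_max:
        raise ValueError("rates must satisfy 0 <= rate_min <= rate_max")
    e = math.exp(-activity / threshold)
    return rate_min * e + rate_max * (1.0 - e)


def step(
    state: TissueState,
    stress: float,
    frequency: float,
    params: TissueParameters | None = None,
    osmo: OsmoticParameters | None = None,
) -> TissueState:
    """Advance the tissue by one day under the given loading.

    The day's equilibrium strain and activity level are computed from
    the day-``t`` state, and all three densities are updated in
    lock-step from day-``t`` values (synchronous update).  Densities are
    clamped at zero; a clamp is logged since it signals rates large
    enough to overshoot in one day.
    """
    if params is None:
        params = TissueParameters()
    if osmo is None:
        osmo = OsmoticParameters()
    if stress < 0:
        raise ValueError(f"stress must be non-negative, got {stress}")
    if frequency < 0:
        raise ValueError(f"frequency must be non-negative, got {frequency}")

    n, a, c = state.chondrocytes, state.aggrecan, state.collagen
    strain = equilibrium_strain(a, stress, osmo)
    act = daily_activity(strain, frequency)

    d_cell = damage_fraction(act, params.sigmoid_cell, params.activity_threshold)
    d_col = damage_fraction(act, params.sigmoid_col, params.activity_threshold)
    synth_a = synthesis_rate(
        act, params.agg_synth_min, params.agg_synth_max, params.activity_threshold
    )
    synth_c = synthesis_rate(
        act, params.col_synth_min, params.col_synth_max, params.activity_threshold
    )

    n_next = n + params.prolif_rate * (1.0 - n / params.healthy_cell_density) * n \
        - params.cell_loss_max * d_cell * n
    a_next = a + synth_a * n - (
        params.agg_loss_base
        + params.agg_loss_extra * math.exp(1.0 - c / params.col_healthy)
    ) * a
    c_next = c + synth_c * n - (
        params.col_loss_base + params.col_damage_max * d_col
    ) * c

    if n_next < 0 or a_next < 0 or c_next < 0:
        logger.debug(
            "negative density clamped at day %d: n=%.3g a=%.3g c=%.3g",
            state.day, n_next, a_next, c_next,
        )
    return TissueState(
        chondrocytes=max(n_next, 0.0),
        aggrecan=max(a_next, 0.0),
        collagen=max(c_next, 0.0),
        day=state.day + 1,
    )


def steady_state(
    params: TissueParameters | None = None,
    osmo: OsmoticParameters | None = None,
    mean_stress: float = 350.0,
    mean_frequency: float = 0.1,
    tolerance: float = 5e-4,
    max_days: int = 20000,
    initial: TissueState | None = None,
) -> TissueState:
    """Iterate the daily map under a constant mean load until stationary.

    Runs :func:`step` with the deterministic mean stress and frequency
    (no random sampling) from ``initial`` until the maximum relative
    per-day change across the three densities falls below ``tolerance``.
    Used to construct a reproducible initial condition for ensemble
    runs.

    Under zero load the map has a genuine fixed point and converges to
    machine precision.  Under physiologic loads the model reaches a
    quasi-stationary plateau that still drifts slowly (there is no
    strict interior fixed point); the loose default tolerance detects
    that plateau, while tight tolerances raise :class:`SteadyStateError`
    carrying the last state.
    """
    if params is None:
        params = TissueParameters()
    if osmo is None:
        osmo = OsmoticParameters()
    if not mean_stress >= 0 or not mean_frequency >= 0:
        raise ValueError("mean stress and frequency must be non-negative")
    if initial is None:
        initial = TissueState(
            chondrocytes=params.healthy_cell_density,
            aggrecan=100.0,
            collagen=params.col_healthy,
        )
    state = initial
    for _ in range(max_days):
        nxt = step(state, mean_stress, mean_frequency, params, osmo)
        rel = max(
            _rel_change(state.chondrocytes, nxt.chondrocytes),
            _rel_change(state.aggrecan, nxt.aggrecan),
            _rel_change(state.collagen, nxt.collagen),
        )
        state = nxt
        if rel < tolerance:
            logger.info(
                "steady state at day %d: n=%.4g a=%.4g c=%.4g (rel change %.2e)",
                state.day, state.chondrocytes, state.aggrecan, state.collagen, rel,
            )
            return replace(state, day=0)
    raise SteadyStateError(
        f"no steady state within {max_days} days at tolerance {tolerance:g} "
        f"(last relative change {rel:.3e})",
        last_state=state,
    )


def _rel_change(old: float, new: float) -> float:
    scale = max(abs(old), 1e-30)
    return abs(new - old) / scale
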