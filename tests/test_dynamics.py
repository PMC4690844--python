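"""Daily damage/repair updates, fixed points and steady states."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chondrosim import (
    SteadyStateError,
    TissueParameters,
    TissueState,
    daily_activity,
    damage_fraction,
    equilibrium_strain,
    step,
    steady_state,
    synthesis_rate,
    tissue_health,
)


def damage_oracle(activity, mu, a0):
    k = 1.0 + math.exp(-mu * a0)
    return k / (1.0 + math.exp(-mu * (activity - a0))) - k / (1.0 + math.exp(mu * a0))


def synthesis_oracle(activity, rmin, rmax, a0):
    e = math.exp(-activity / a0)
    return rmin * e + rmax * (1.0 - e)


class TestDailyActivity:
    @pytest.mark.parametrize(
        "strain,freq,expected",
        [
            (0.30, 0.3, 0.09),  # the activity threshold itself
            (0.0, 0.5, 0.0),
            (0.13, 0.1, 0.013),
        ],
    )
    def test_product(self, strain, freq, expected):
        assert daily_activity(strain, freq) == pytest.approx(expected, rel=1e-12)

    def test_zero_iff_either_factor_zero(self):
        assert daily_activity(0.25, 0.0) == 0.0
        assert daily_activity(0.25, 0.1) > 0.0

    def test_domain(self):
        with pytest.raises(ValueError):
            daily_activity(1.0, 0.1)
        with pytest.raises(ValueError):
            daily_activity(0.2, -0.1)


class TestDamageFraction:
    @pytest.mark.parametrize("mu", [10.0, 50.0, 100.0, 500.0])
    def test_zero_activity_gives_exactly_zero(self, mu):
        assert damage_fraction(0.0, mu, 0.09) == 0.0

    @pytest.mark.parametrize(
        "activity,mu,expected",
        [
            (0.09, 50.0, 0.4944455017308788),
            (0.09, 100.0, 0.4999382950979567),
        ],
    )
    def test_reference_values(self, activity, mu, expected):
        assert damage_fraction(activity, mu, 0.09) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("mu", [50.0, 100.0])
    def test_saturates_at_one(self, mu):
        assert damage_fraction(1e9, mu, 0.09) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(0.0, 0.5, 200)
        d = [damage_fraction(a, 50.0, 0.09) for a in grid]
        assert all(d2 > d1 for d1, d2 in zip(d, d[1:]))

    def test_matches_formula_oracle_on_grid(self):
        for a in np.linspace(0.0, 0.4, 100):
            for mu in (50.0, 100.0):
                assert damage_fraction(a, mu, 0.09) == pytest.approx(
                    damage_oracle(a, mu, 0.09), abs=1e-12
                )

    def test_extreme_steepness_does_not_overflow(self):
        assert damage_fraction(0.0, 1e5, 0.09) == 0.0
        assert damage_fraction(1.0, 1e5, 0.09) == pytest.approx(1.0, abs=1e-9)


class TestSynthesisRate:
    def test_endpoints(self):
        assert synthesis_rate(0.0, 1.1e-8, 1.65e-8, 0.09) == 1.1e-8
        assert synthesis_rate(100.0, 1.1e-8, 1.65e-8, 0.09) == pytest.approx(
            1.65e-8, rel=1e-12
        )

    def test_value_at_threshold(self):
        expected = 1.1e-8 / math.e + 1.65e-8 * (1.0 - 1.0 / math.e)
        assert synthesis_rate(0.09, 1.1e-8, 1.65e-8, 0.09) == pytest.approx(
            expected, rel=1e-12
        )

    def test_reference_value(self):
        assert synthesis_rate(0.013, 1.1e-8, 1.65e-8, 0.09) == pytest.approx(
            1.1739733529880526e-08, rel=1e-12
        )

    def test_matches_formula_oracle_on_grid(self):
        for a in np.linspace(0.0, 0.5, 100):
            assert synthesis_rate(a, 1.1e-8, 1.65e-8, 0.09) == pytest.approx(
                synthesis_oracle(a, 1.1e-8, 1.65e-8, 0.09), rel=1e-12
            )

    def test_monotone_toward_max(self):
        grid = np.linspace(0.0, 1.0, 50)
        r = [synthesis_rate(a, 1.1e-8, 1.65e-8, 0.09) for a in grid]
        assert all(r2 > r1 for r1, r2 in zip(r, r[1:]))


class TestStep:
    def test_healthy_cells_unloaded_are_a_fixed_point(self, params, osmo):
        state = TissueState(params.healthy_cell_density, 90.0, params.col_healthy)
        nxt = step(state, stress=0.0, frequency=0.0, params=params, osmo=osmo)
        # logistic term vanishes at n0 and D(0) = 0, so cells are unchanged
        assert nxt.chondrocytes == state.chondrocytes
        assert nxt.day == 1

    def test_acellular_decay_rates(self, params, osmo):
        """With no cells and healthy collagen, matrix decays at the base rates."""
        state = TissueState(0.0, 80.0, params.col_healthy)
        nxt = step(state, stress=0.0, frequency=0.0, params=params, osmo=osmo)
        # aggrecan: loss (0.01 + 0.005 e^0) = 1.5%/day
        assert nxt.aggrecan == pytest.approx(80.0 * (1.0 - 0.015), rel=1e-12)
        # collagen: D(0) = 0, so only the 0.6%/day proteolytic loss
        assert nxt.collagen == pytest.approx(params.col_healthy * 0.994, rel=1e-12)

    def test_zero_rates_identity(self, osmo):
        params = TissueParameters(
            prolif_rate=0.0, cell_loss_max=0.0,
            agg_synth_min=0.0, agg_synth_max=0.0,
            agg_loss_base=0.0, agg_loss_extra=0.0,
            col_synth_min=0.0, col_synth_max=0.0,
            col_loss_base=0.0, col_damage_max=0.0,
        )
        state = TissueState(5e7, 90.0, 150.0)
        nxt = step(state, stress=500.0, frequency=0.2, params=params, osmo=osmo)
        assert (nxt.chondrocytes, nxt.aggrecan, nxt.collagen) == (5e7, 90.0, 150.0)

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.floats(0.0, 5e8),
        a=st.floats(1e-3, 300.0),
        c=st.floats(0.0, 500.0),
        stress=st.floats(0.0, 5000.0),
        freq=st.floats(0.0, 2.0),
    )
    def test_densities_never_negative(self, n, a, c, stress, freq):
        state = TissueState(n, a, c)
        nxt = step(state, stress, freq)
        assert nxt.chondrocytes >= 0.0
        assert nxt.aggrecan >= 0.0
        assert nxt.collagen >= 0.0

    @pytest.mark.parametrize(
        "target_activity,expected_frac",
        [
            (0.05, None),  # D < 0.2: survives at n0 * (1 - 5 D)
            (0.08, 0.0),  # D > 0.2: extinction
        ],
    )
    def test_chondrocyte_logistic_fixed_points(
        self, target_activity, expected_frac, params, osmo
    ):
        """Constant damage D drives n -> n0(1 - 5D) if D < 0.2, else 0."""
        a_fixed, stress = 90.0, 600.0
        strain = equilibrium_strain(a_fixed, stress, osmo)
        freq = target_activity / strain
        d = damage_fraction(
            target_activity, params.sigmoid_cell, params.activity_threshold
        )
        if expected_frac is None:
            expected = params.healthy_cell_density * (
                1.0 - params.cell_loss_max / params.prolif_rate * d
            )
            assert d < 0.2
        else:
            expected = 0.0
            assert d > 0.2
        n = params.healthy_cell_density
        for _ in range(25000):
            state = TissueState(n, a_fixed, params.col_healthy)
            n = step(state, stress, freq, params, osmo).chondrocytes
        assert n == pytest.approx(expected, rel=2e-3, abs=1e3)

    def test_aggrecan_contraction_with_cells_pinned(self, params, osmo):
        """At n = n0 and constant load the aggrecan map converges monotonely."""
        rng = np.random.default_rng(11)
        finals = []
        for a0 in rng.uniform(20.0, 150.0, 10):
            a = float(a0)
            prev_gap = None
            for t in range(4000):
                state = TissueState(params.healthy_cell_density, a, params.col_healthy)
                a_next = step(state, 350.0, 0.1, params, osmo).aggrecan
                gap = abs(a_next - a)
                if prev_gap is not None and t > 5:
                    assert gap <= prev_gap + 1e-12
                prev_gap = gap
                a = a_next
            finals.append(a)
        assert np.ptp(finals) < 1e-6


class TestSteadyState:
    def test_zero_load_fixed_point_closed_form(self, params, osmo):
        state = steady_state(
            params, osmo, mean_stress=0.0, mean_frequency=0.0,
            tolerance=1e-10, max_days=50000,
        )
        n0 = params.healthy_cell_density
        c_star = params.col_synth_min * n0 / params.col_loss_base
        a_star = params.agg_synth_min * n0 / (
            params.agg_loss_base
            + params.agg_loss_extra * math.exp(1.0 - c_star / params.col_healthy)
        )
        assert state.chondrocytes == pytest.approx(n0, rel=1e-6)
        assert state.collagen == pytest.approx(c_star, rel=1e-6)
        assert state.aggrecan == pytest.approx(a_star, rel=1e-6)

    def test_medium_profile_quasi_steady_plateau(self, medium_quasi_steady, params):
        state = medium_quasi_steady
        assert state.chondrocytes == pytest.approx(
            params.healthy_cell_density, rel=0.05
        )
        assert 75.0 <= state.aggrecan <= 95.0
        assert tissue_health(state.aggrecan) > 0.0
        assert state.day == 0  # usable as a fresh initial condition

    def test_medium_profile_has_no_strict_fixed_point(self, params, osmo):
        """At tight tolerance the slow drift never stops: explicit error."""
        with pytest.raises(SteadyStateError) as err:
            steady_state(
                params, osmo, mean_stress=350.0, mean_frequency=0.1,
                tolerance=1e-8, max_days=2000,
            )
        assert err.value.last_state.aggrecan > 0.0

    def test_nonconvergence_error_carries_state(self, params, osmo):
        with pytest.raises(SteadyStateError) as err:
            steady_state(params, osmo, tolerance=0.0, max_days=10)
        assert isinstance(err.value.last_state, TissueState)
        assert err.value.last_state.day == 10


class TestTissueParameters:
    def test_defaults_satisfy_published_ratios(self, params):
        assert params.agg_synth_max == pytest.approx(1.5 * params.agg_synth_min)
        assert params.col_synth_max == pytest.approx(1.5 * params.col_synth_min)
        assert params.activity_threshold == pytest.approx(0.30 * 0.3)

    def test_validation(self):
        with pytest.raises(ValueError, match="col_healthy"):
            TissueParameters(col_healthy=0.0)
        with pytest.raises(ValueError, match="agg_synth_max"):
            TissueParameters(agg_synth_min=2e-8, agg_synth_max=1e-8)
        with pytest.raises(ValueError, match="non-negative"):
            dataclasses.replace(TissueParameters(), prolif_rate=-0.1)
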