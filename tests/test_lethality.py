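"""Inactivation kinetics: D/z law, F integration, 12D detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ohmicpast import (
    KineticsParams,
    accumulate_lethality,
    decimal_reduction_time,
    lethal_rate,
    log_reduction,
    survivor_curve,
    time_to_target,
)

PARAMS = KineticsParams(z=10.0, D_ref=60.0, T_ref=333.15)


def test_d_value_at_reference_and_one_z_above():
    assert decimal_reduction_time(PARAMS, 333.15) == pytest.approx(60.0, rel=1e-14)
    assert decimal_reduction_time(PARAMS, 343.15) == pytest.approx(6.0, rel=1e-14)
    assert decimal_reduction_time(PARAMS, 323.15) == pytest.approx(600.0, rel=1e-14)


def test_holding_one_d_kills_ninety_percent():
    """Holding at the reference temperature for one D-value removes 1 log."""
    t = np.linspace(0.0, PARAMS.D_ref, 61)
    N = survivor_curve(1.0, t, np.full_like(t, PARAMS.T_ref), PARAMS)
    assert N[-1] == pytest.approx(0.1, rel=1e-12)


@pytest.mark.parametrize(
    "T,expected_F", [(333.15, 600.0), (323.15, 60.0), (343.15, 6000.0)]
)
def test_constant_temperature_lethality(T, expected_F):
    F = np.zeros((2, 2))
    Tf = np.full((2, 2), T)
    for _ in range(100):
        F = accumulate_lethality(F, Tf, Tf, PARAMS, 6.0)
    assert np.allclose(F, expected_F, rtol=1e-12)


def test_accumulation_is_additive_over_subintervals():
    rng = np.random.default_rng(11)
    T = 300.0 + 60.0 * rng.random(101)
    dt = 0.5
    F_whole = np.zeros(1)
    for k in range(100):
        F_whole = accumulate_lethality(F_whole, T[k : k + 1], T[k + 1 : k + 2], PARAMS, dt)
    F_a = np.zeros(1)
    for k in range(40):
        F_a = accumulate_lethality(F_a, T[k : k + 1], T[k + 1 : k + 2], PARAMS, dt)
    F_b = F_a.copy()
    for k in range(40, 100):
        F_b = accumulate_lethality(F_b, T[k : k + 1], T[k + 1 : k + 2], PARAMS, dt)
    assert F_b[0] == pytest.approx(F_whole[0], rel=1e-14)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_warmer_profiles_accumulate_at_least_as_much(seed):
    rng = np.random.default_rng(seed)
    T = 300.0 + 50.0 * rng.random(20)
    bump = 5.0 * rng.random(20)
    F_cold = np.zeros(1)
    F_warm = np.zeros(1)
    for k in range(19):
        F_cold = accumulate_lethality(F_cold, T[k : k + 1], T[k + 1 : k + 2], PARAMS, 1.0)
        Tw = T + bump
        F_warm = accumulate_lethality(F_warm, Tw[k : k + 1], Tw[k + 1 : k + 2], PARAMS, 1.0)
    assert F_warm[0] >= F_cold[0]


def test_time_to_target_constant_reference_temperature():
    times = np.arange(0.0, 801.0, 10.0)
    lr = times / 60.0  # holding at T_ref: one log per D_ref
    assert time_to_target(times, lr, PARAMS) == pytest.approx(720.0, rel=1e-12)


def test_time_to_target_tenfold_rate_and_min_over_cells():
    times = np.arange(0.0, 801.0, 10.0)
    fast = 10.0 * times / 60.0  # cell at T_ref + z
    slow = times / 60.0
    assert time_to_target(times, fast, PARAMS) == pytest.approx(72.0, rel=1e-12)
    # the governing time is the slower cell's
    assert time_to_target(times, np.minimum(fast, slow), PARAMS) == pytest.approx(720.0)


def test_time_to_target_sentinel_and_errors():
    assert math.isnan(time_to_target(np.array([0.0, 10.0]), np.array([0.0, 1.0]), PARAMS))
    with pytest.raises(ValueError):
        time_to_target(np.array([]), np.array([]), PARAMS)


def test_survivor_curve_matches_stiff_ode_oracle():
    """N(t) = N0·10^(−F/D_ref) agrees with direct ODE integration on a ramp."""
    t_end = 600.0
    times = np.arange(0.0, t_end + 0.125, 0.125)
    T_of_t = lambda t: 323.15 + 25.0 * t / t_end  # 50 → 75 °C ramp

    def rhs(t, y):
        D = decimal_reduction_time(PARAMS, T_of_t(t))
        return [-math.log(10.0) / D * y[0]]

    sol = solve_ivp(rhs, (0.0, t_end), [1e6], method="LSODA", rtol=1e-10, atol=1e-30)
    N = survivor_curve(1e6, times, T_of_t(times), PARAMS)
    assert N[-1] == pytest.approx(sol.y[0, -1], rel=1e-6)
    assert np.all(np.diff(N) <= 0.0)


def test_survivor_curve_consistent_with_log_reduction():
    rng = np.random.default_rng(5)
    times = np.linspace(0.0, 300.0, 301)
    T = 320.0 + np.cumsum(rng.uniform(0, 0.2, size=301))
    N = survivor_curve(1e6, times, T, PARAMS)
    F = np.zeros(1)
    for k in range(300):
        F = accumulate_lethality(F, T[k : k + 1], T[k + 1 : k + 2], PARAMS,
                                 times[k + 1] - times[k])
    assert np.log10(1e6 / N[-1]) == pytest.approx(log_reduction(F[0], PARAMS), rel=1e-12)


def test_lethal_rate_reference_values():
    assert lethal_rate(PARAMS, PARAMS.T_ref) == 1.0
    assert lethal_rate(PARAMS, PARAMS.T_ref - PARAMS.z) == pytest.approx(0.1)


def test_invalid_kinetics_rejected():
    with pytest.raises(ValueError):
        KineticsParams(z=0.0)
    with pytest.raises(ValueError):
        KineticsParams(D_ref=-1.0)
    with pytest.raises(ValueError):
        survivor_curve(0.0, np.array([0.0, 1.0]), np.array([300.0, 300.0]), PARAMS)
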