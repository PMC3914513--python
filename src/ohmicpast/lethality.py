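"""First-order thermal inactivation kinetics (D/z/F values).

The survivor population obeys ``dN/dt = −(ln 10 / D(T)) · N`` with the
decimal reduction time following the classical z-value law
``D(T) = D_ref · 10^((T_ref − T)/z)``.  Integrating gives the log
reduction ``log10(N0/N) = F / D_ref`` where

    F(t) = ∫₀ᵗ 10^((T − T_ref)/z) dτ

is the accumulated lethality (sterility factor): the equivalent time at
``T_ref`` delivered by the actual time-temperature history.  A process is
deemed complete when the *minimum over the product* of the log reduction
reaches the target (12 decades for a 12D pasteurization), since safety is
governed by the least-treated location.

Defaults target Escherichia coli O157:H7 with the classical ``z = 10 °C``;
the reference point ``D_ref = 60 s at 60 °C`` is a literature-scale
assumption (only z is tightly constrained) and both are configurable —
absolute process times scale directly with this choice, relative
comparisons between scenarios do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN10 = math.log(10.0)

#: Sentinel returned when a run ends before reaching the target reduction.
NOT_REACHED = math.nan


@dataclass(frozen=True)
class KineticsParams:
    """Inactivation parameters of the target microorganism.

    Attributes
    ----------
    z : float
        Temperature rise [°C ≡ K] that divides the D-value by ten.
    D_ref : float
        Decimal reduction time [s] at the reference temperature.
    T_ref : float
        Reference temperature [K].
    target_log_reduction : float
        Decades of reduction defining process completion (12 ⇒ "12D").
    """

    z: float = 10.0
    D_ref: float = 60.0
    T_ref: float = 333.15
    target_log_reduction: float = 12.0

    def __post_init__(self) -> None:
        if self.z <= 0.0:
            raise ValueError("z must be positive")
        if self.D_ref <= 0.0:
            raise ValueError("D_ref must be positive")
        if self.target_log_reduction <= 0.0:
            raise ValueError("target_log_reduction must be positive")


def decimal_reduction_time(params: KineticsParams, T: "float | np.ndarray"):
    """D-value [s] at temperature ``T`` [K]: ``D_ref·10^((T_ref−T)/z)``."""
    return params.D_ref * 10.0 ** ((params.T_ref - np.asarray(T, float)) / params.z)


def lethal_rate(params: KineticsParams, T: "float | np.ndarray"):
    """Dimensionless lethal rate ``10^((T−T_ref)/z)``, the F integrand."""
    return 10.0 ** ((np.asarray(T, float) - params.T_ref) / params.z)


def accumulate_lethality(
    F: np.ndarray,
    T_start: np.ndarray,
    T_end: np.ndarray,
    params: KineticsParams,
    dt: float,
) -> np.ndarray:
    """Advance the accumulated lethality over one step of length ``dt`` [s].

    Trapezoidal rule on the step's endpoint temperatures, consistent in
    order with the thermal time stepping.  Returns the new F field;
    accumulation over subintervals is exactly additive.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    inc = 0.5 * (lethal_rate(params, T_start) + lethal_rate(params, T_end)) * dt
    return np.asarray(F, float) + inc


def log_reduction(F: "float | np.ndarray", params: KineticsParams):
    """Decades of reduction delivered by accumulated lethality ``F``."""
    return np.asarray(F, float) / params.D_ref


def time_to_target(
    times: np.ndarray,
    min_log_reduction: np.ndarray,
    params: KineticsParams,
) -> float:
    """First time [s] the minimum-over-cells log reduction hits the target.

    Linearly interpolates within the bracketing step; returns the
    ``NOT_REACHED`` sentinel (NaN) if the history ends below target.
    """
    times = np.asarray(times, float)
    lr = np.asarray(min_log_reduction, float)
    if times.size == 0 or lr.size != times.size:
        raise ValueError("empty or mismatched lethality history")
    target = params.target_log_reduction
    hit = np.nonzero(lr >= target)[0]
    if hit.size == 0:
        return NOT_REACHED
    k = int(hit[0])
    if k == 0:
        return float(times[0])
    frac = (target - lr[k - 1]) / (lr[k] - lr[k - 1])
    return float(times[k - 1] + frac * (times[k] - times[k - 1]))


def survivor_curve(
    N0: float,
    times: np.ndarray,
    T_profile: np.ndarray,
    params: KineticsParams,
) -> np.ndarray:
    """Survivor population ``N(t)`` along a time-temperature profile.

    ``N(t) = N0 · 10^(−F(t)/D_ref)`` with F integrated by the trapezoid
    rule over the sampled profile; strictly nonincreasing.
    """
    if N0 <= 0.0:
        raise ValueError("N0 must be positive")
    times = np.asarray(times, float)
    rates = lethal_rate(params, np.asarray(T_profile, float))
    if times.shape != rates.shape:
        raise ValueError("times and T_profile must have the same shape")
    F = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rates[1:] + rates[:-1]) * np.diff(times))]
    )
    return N0 * 10.0 ** (-F / params.D_ref)
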