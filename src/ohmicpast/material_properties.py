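"""Temperature-dependent thermophysical and electrical properties.

Properties of the sample (thermal conductivity ``λ``, volumetric heat
capacity ``VHC = ρ·Cp`` and electrical conductivity ``σ``) are supplied as
small measured tables versus temperature and evaluated by piecewise-linear
interpolation.  Outside the measured range the nearest tabulated value is
held constant (clamped extrapolation), which keeps every property bounded
and positive if a transient briefly overshoots the measured range.

All temperatures at the API surface are kelvin; tables are constructed from
Celsius because that is how such measurements are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

CELSIUS_OFFSET = 273.15

#: Valid property names, in table-column order.
PROPERTY_NAMES = (
    "thermal_conductivity",
    "volumetric_heat_capacity",
    "electrical_conductivity",
)


@dataclass(frozen=True)
class PropertyTable:
    """Tabulated sample properties versus temperature.

    Parameters
    ----------
    temperatures_c
        Strictly increasing measurement temperatures, °C.
    thermal_conductivity
        λ at each temperature, W m⁻¹ K⁻¹.
    volumetric_heat_capacity
        ρ·Cp at each temperature, J m⁻³ K⁻¹ (SI, not MJ).
    electrical_conductivity
        σ at each temperature, S m⁻¹.
    """

    temperatures_c: np.ndarray
    thermal_conductivity: np.ndarray
    volumetric_heat_capacity: np.ndarray
    electrical_conductivity: np.ndarray

    def __post_init__(self) -> None:
        for name in ("temperatures_c",) + PROPERTY_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
        n = self.temperatures_c.size
        if n < 2:
            raise ValueError("property table needs at least two temperatures")
        if not np.all(np.diff(self.temperatures_c) > 0):
            raise ValueError("temperatures must be strictly increasing")
        for name in PROPERTY_NAMES:
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError(
                    f"{name} has {arr.size} entries, expected {n} "
                    "(one per temperature)"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
                raise ValueError(f"{name} values must be finite and positive")

    @classmethod
    def mashed_potato(cls) -> "PropertyTable":
        """Packaged default: measured mashed-potato properties, 5–85 °C."""
        return cls(
            temperatures_c=np.array([5.0, 25.0, 45.0, 65.0, 85.0]),
            thermal_conductivity=np.array([0.409, 0.451, 0.490, 0.532, 0.571]),
            volumetric_heat_capacity=1.0e6
            * np.array([3.339, 3.383, 3.441, 3.496, 3.589]),
            electrical_conductivity=np.array([1.228, 1.991, 2.756, 3.514, 4.278]),
        )

    def with_conductivity_scale(self, factor: float) -> "PropertyTable":
        """Return a copy with σ(T) multiplied uniformly by ``factor``."""
        if factor <= 0.0:
            raise ValueError("conductivity scale factor must be positive")
        return replace(
            self, electrical_conductivity=self.electrical_conductivity * factor
        )

    def evaluate(self, which: str, T: "float | np.ndarray"):
        """Evaluate one property at temperature(s) ``T`` (kelvin)."""
        return evaluate_property(self, which, T)


def evaluate_property(
    table: PropertyTable, which: str, T: "float | np.ndarray"
) -> "float | np.ndarray":
    """Interpolate property ``which`` of ``table`` at temperature ``T`` [K].

    Piecewise-linear between tabulated points, clamped (constant) outside
    the tabulated range.  Scalar in, scalar out; array in, array out.
    """
    if which not in PROPERTY_NAMES:
        raise KeyError(
            f"unknown property {which!r}; expected one of {PROPERTY_NAMES}"
        )
    T_arr = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T_arr)):
        raise ValueError("temperature must be finite")
    # np.interp clamps to the end values outside the table by default.
    out = np.interp(T_arr - CELSIUS_OFFSET, table.temperatures_c, getattr(table, which))
    return float(out) if np.isscalar(T) or T_arr.ndim == 0 else out


def property_fields(
    table: PropertyTable, T_field: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate (λ, VHC, σ) fields for a per-cell temperature field [K]."""
    lam = evaluate_property(table, "thermal_conductivity", T_field)
    vhc = evaluate_property(table, "volumetric_heat_capacity", T_field)
    sigma = evaluate_property(table, "electrical_conductivity", T_field)
    return lam, vhc, sigma
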