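"""Process-parameter sensitivity suite and cold-spot classification.

Seven built-in cases vary the exterior heat exchange (coefficient ``U`` and
ambient temperature ``T_inf``) and the sample's electrical conductivity
(±10 %) around an insulated control, all at 100 V constant voltage:

======  ====================  ===========  ========
case    U [W m⁻² K⁻¹]         T_inf [K]    σ scale
======  ====================  ===========  ========
C1      0 (insulated)         —            1.00
C2      0                     —            1.10
C3      0                     —            0.90
C4      5                     286.15       1.00
C5      5                     314.15       1.00
C6      15                    286.15       1.00
C7      15                    314.15       1.00
======  ====================  ===========  ========

Each case is run until the cold spot accumulates the target log reduction
(extending past the base process time when necessary), and the suite
reports the 12D time, its percent change versus the control, the cold-spot
class and the final temperature extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lethality import KineticsParams
from .material_properties import PropertyTable
from .mesh import AxisymMesh
from .simulate import ProcessConfig, SimulationTrace, run_simulation
from .thermal import ThermalBC

COLD_SPOT_CLASSES = ("uniform", "exterior-corner", "on-axis", "interior")


@dataclass(frozen=True)
class ScenarioSpec:
    """One sensitivity case: exterior exchange and conductivity scaling."""

    name: str
    U: float = 0.0
    T_inf: float = 286.15
    sigma_scale: float = 1.0
    drive_mode: str = "constant_voltage"

    def __post_init__(self) -> None:
        if self.sigma_scale <= 0.0:
            raise ValueError("sigma_scale must be positive")
        if self.U < 0.0:
            raise ValueError("U must be nonnegative")


@dataclass
class ScenarioResult:
    """Outcome of one scenario run."""

    spec: ScenarioSpec
    t12d: float  # s; NaN if the cap was hit first
    pct_vs_control: float  # %
    cold_spot_class: str
    final_T_min: float  # K
    final_T_max: float  # K
    trace: SimulationTrace


def builtin_cases() -> list[ScenarioSpec]:
    """The seven built-in sensitivity cases (C1 is the control)."""
    return [
        ScenarioSpec("C1", U=0.0),
        ScenarioSpec("C2", U=0.0, sigma_scale=1.10),
        ScenarioSpec("C3", U=0.0, sigma_scale=0.90),
        ScenarioSpec("C4", U=5.0, T_inf=286.15),
        ScenarioSpec("C5", U=5.0, T_inf=314.15),
        ScenarioSpec("C6", U=15.0, T_inf=286.15),
        ScenarioSpec("C7", U=15.0, T_inf=314.15),
    ]


def classify_cold_spot(
    F: np.ndarray, mesh: AxisymMesh, uniformity_threshold: float = 0.01
) -> str:
    """Classify the cold-spot location from a final lethality field.

    ``uniform`` if the relative spread ``(Fmax − Fmin)/Fmax`` is below the
    threshold (no identifiable cold area); otherwise ``exterior-corner`` if
    the least-treated cell sits in the outermost ring *and* an outermost
    axial layer (the electrode/lateral-surface junction); ``on-axis`` if it
    sits on the symmetry axis; ``interior`` otherwise.
    """
    F = np.asarray(F, dtype=float)
    fmax = float(F.max())
    if fmax <= 0.0:
        return "uniform"
    if (fmax - float(F.min())) / fmax < uniformity_threshold:
        return "uniform"
    i, j = np.unravel_index(int(np.argmin(F)), F.shape)
    if i == mesh.nr - 1 and j in (0, mesh.nz - 1):
        return "exterior-corner"
    if i == 0:
        return "on-axis"
    return "interior"


def run_suite(
    specs: list[ScenarioSpec],
    base: ProcessConfig,
    kinetics: KineticsParams | None = None,
    *,
    hard_cap: float = 3600.0,
    uniformity_threshold: float = 0.01,
) -> list[ScenarioResult]:
    """Run every scenario and compare against the first (control) one.

    Each run continues until the target log reduction is reached at the
    cold spot, auto-extending beyond ``base.duration`` up to ``hard_cap``
    seconds; an unreached target is reported as NaN, not raised.
    """
    if not specs:
        raise ValueError("no scenarios given")
    kinetics = kinetics or KineticsParams()
    table = PropertyTable.mashed_potato()
    results: list[ScenarioResult] = []
    t_control = None
    for spec in specs:
        cfg = replace(
            base,
            thermal_bc=ThermalBC(
                U=spec.U,
                T_inf=spec.T_inf,
                electrode_bottom=base.thermal_bc.electrode_bottom,
                electrode_top=base.thermal_bc.electrode_top,
                lateral=base.thermal_bc.lateral,
            ),
            sigma_scale=spec.sigma_scale,
            drive_mode=spec.drive_mode,
        )
        trace = run_simulation(
            cfg, table, kinetics, until_target=True, hard_cap=hard_cap
        )
        t12d = trace.time_to_target(kinetics)
        if t_control is None:
            t_control = t12d
            pct = 0.0
        else:
            pct = 100.0 * (t12d - t_control) / t_control
        results.append(
            ScenarioResult(
                spec=spec,
                t12d=t12d,
                pct_vs_control=pct,
                cold_spot_class=classify_cold_spot(
                    trace.F_final, trace.mesh, uniformity_threshold
                ),
                final_T_min=float(trace.T_final.min()),
                final_T_max=float(trace.T_final.max()),
                trace=trace,
            )
        )
    return results


def report_dataframe(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tabular scenario report (one row per case, units in column names)."""
    return pd.DataFrame(
        {
            "scenario": [r.spec.name for r in results],
            "U_W_m2K": [r.spec.U for r in results],
            "T_inf_K": [r.spec.T_inf for r in results],
            "sigma_scale": [r.spec.sigma_scale for r in results],
            "t12D_s": [r.t12d for r in results],
            "pct_vs_control": [r.pct_vs_control for r in results],
            "cold_spot_class": [r.cold_spot_class for r in results],
            "Tmin_K": [r.final_T_min for r in results],
            "Tmax_K": [r.final_T_max for r in results],
        }
    )
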