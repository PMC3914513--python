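"""Configuration loading and validation.

Runs are described by a structured YAML file with nested sections
(``geometry``, ``grid``, ``process``, ``thermal_bc``, ``kinetics``,
``properties``, ``scenarios``).  Every field has a default reproducing the
baseline process (100 V, 279.15 K initial temperature, 150 s); unknown keys
are rejected with the exact field path, never silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .lethality import KineticsParams
from .material_properties import PropertyTable
from .mesh import CylinderGeometry
from .scenarios import ScenarioSpec, builtin_cases
from .simulate import ProcessConfig
from .thermal import ThermalBC


class ConfigError(ValueError):
    """Invalid or unknown configuration field (message names the path)."""


@dataclass
class RunConfiguration:
    """Fully validated configuration bundle for a run or a suite."""

    process: ProcessConfig
    kinetics: KineticsParams
    table: PropertyTable
    scenarios: list[ScenarioSpec] = field(default_factory=builtin_cases)

    def echo(self) -> dict:
        """Round-trippable plain-dict form (re-parses to an identical bundle)."""
        p = self.process
        return {
            "geometry": {
                "radius_m": p.geometry.radius,
                "length_m": p.geometry.length,
            },
            "grid": {"nr": p.nr, "nz": p.nz},
            "process": {
                "applied_voltage_V": p.applied_voltage,
                "drive_mode": p.drive_mode,
                "duration_s": p.duration,
                "dt_s": p.dt,
                "T0_K": p.T0,
                "sigma_scale": p.sigma_scale,
                "target_power_W": p.target_power,
                "snapshot_interval_s": p.snapshot_interval,
                "max_temperature_K": p.max_temperature,
            },
            "thermal_bc": {
                "U_W_m2K": p.thermal_bc.U,
                "T_inf_K": p.thermal_bc.T_inf,
                "electrode_bottom": p.thermal_bc.electrode_bottom,
                "electrode_top": p.thermal_bc.electrode_top,
                "lateral": p.thermal_bc.lateral,
            },
            "kinetics": {
                "z_C": self.kinetics.z,
                "D_ref_s": self.kinetics.D_ref,
                "T_ref_K": self.kinetics.T_ref,
                "target_log_reduction": self.kinetics.target_log_reduction,
            },
            "properties": {
                "T_celsius": self.table.temperatures_c.tolist(),
                "lambda_W_mK": self.table.thermal_conductivity.tolist(),
                "vhc_MJ_m3K": (self.table.volumetric_heat_capacity / 1e6).tolist(),
                "sigma_S_m": self.table.electrical_conductivity.tolist(),
            },
            "scenarios": [
                {
                    "name": s.name,
                    "U_W_m2K": s.U,
                    "T_inf_K": s.T_inf,
                    "sigma_scale": s.sigma_scale,
                    "drive_mode": s.drive_mode,
                }
                for s in self.scenarios
            ],
        }


def _section(data: dict, name: str, allowed: tuple[str, ...]) -> dict:
    sec = data.pop(name, {}) or {}
    if not isinstance(sec, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    for key in sec:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {name}.{key}; allowed: {', '.join(allowed)}"
            )
    return sec


def _number(sec: dict, path: str, key: str, default, *, positive=False, nonneg=False):
    val = sec.get(key, default)
    if val is None:
        return None
    try:
        val = float(val)
    except (TypeError, ValueError):
        raise ConfigError(f"{path}.{key} must be a number, got {val!r}") from None
    if positive and val <= 0.0:
        raise ConfigError(f"{path}.{key} must be positive, got {val}")
    if nonneg and val < 0.0:
        raise ConfigError(f"{path}.{key} must be nonnegative, got {val}")
    return val


def parse_config(data: dict | None) -> RunConfiguration:
    """Validate a parsed mapping into a :class:`RunConfiguration`."""
    data = dict(data or {})

    geo = _section(data, "geometry", ("radius_m", "length_m"))
    grid = _section(data, "grid", ("nr", "nz"))
    proc = _section(
        data,
        "process",
        (
            "applied_voltage_V", "drive_mode", "duration_s", "dt_s", "T0_K",
            "sigma_scale", "target_power_W", "snapshot_interval_s",
            "max_temperature_K",
        ),
    )
    tbc = _section(
        data,
        "thermal_bc",
        ("U_W_m2K", "T_inf_K", "electrode_bottom", "electrode_top", "lateral"),
    )
    kin = _section(
        data, "kinetics", ("z_C", "D_ref_s", "T_ref_K", "target_log_reduction")
    )
    props = _section(
        data, "properties", ("T_celsius", "lambda_W_mK", "vhc_MJ_m3K", "sigma_S_m")
    )
    scen_raw = data.pop("scenarios", None)
    if data:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(data))}")

    try:
        geometry = CylinderGeometry(
            radius=_number(geo, "geometry", "radius_m", 0.025, positive=True),
            length=_number(geo, "geometry", "length_m", 0.18, positive=True),
        )
        thermal_bc = ThermalBC(
            U=_number(tbc, "thermal_bc", "U_W_m2K", 0.0, nonneg=True),
            T_inf=_number(tbc, "thermal_bc", "T_inf_K", 286.15, positive=True),
            electrode_bottom=bool(tbc.get("electrode_bottom", True)),
            electrode_top=bool(tbc.get("electrode_top", True)),
            lateral=bool(tbc.get("lateral", True)),
        )
        process = ProcessConfig(
            geometry=geometry,
            nr=int(grid.get("nr", 24)),
            nz=int(grid.get("nz", 48)),
            applied_voltage=_number(
                proc, "process", "applied_voltage_V", 100.0, positive=True
            ),
            drive_mode=str(proc.get("drive_mode", "constant_voltage")),
            duration=_number(proc, "process", "duration_s", 150.0, positive=True),
            dt=_number(proc, "process", "dt_s", 0.5, positive=True),
            T0=_number(proc, "process", "T0_K", 279.15, positive=True),
            thermal_bc=thermal_bc,
            sigma_scale=_number(proc, "process", "sigma_scale", 1.0, positive=True),
            target_power=_number(proc, "process", "target_power_W", None, positive=True),
            snapshot_interval=_number(
                proc, "process", "snapshot_interval_s", None, positive=True
            ),
            max_temperature=_number(
                proc, "process", "max_temperature_K", 373.15, positive=True
            ),
        )
        kinetics = KineticsParams(
            z=_number(kin, "kinetics", "z_C", 10.0, positive=True),
            D_ref=_number(kin, "kinetics", "D_ref_s", 60.0, positive=True),
            T_ref=_number(kin, "kinetics", "T_ref_K", 333.15, positive=True),
            target_log_reduction=_number(
                kin, "kinetics", "target_log_reduction", 12.0, positive=True
            ),
        )
        if props:
            required = ("T_celsius", "lambda_W_mK", "vhc_MJ_m3K", "sigma_S_m")
            missing = [k for k in required if k not in props]
            if missing:
                raise ConfigError(
                    f"properties table incomplete; missing {', '.join(missing)}"
                )
            table = PropertyTable(
                temperatures_c=np.asarray(props["T_celsius"], float),
                thermal_conductivity=np.asarray(props["lambda_W_mK"], float),
                volumetric_heat_capacity=1e6 * np.asarray(props["vhc_MJ_m3K"], float),
                electrical_conductivity=np.asarray(props["sigma_S_m"], float),
            )
        else:
            table = PropertyTable.mashed_potato()

        if scen_raw is None:
            scenarios = builtin_cases()
        else:
            if not isinstance(scen_raw, list):
                raise ConfigError("scenarios must be a list of mappings")
            scenarios = []
            for k, entry in enumerate(scen_raw):
                entry = dict(entry or {})
                allowed = ("name", "U_W_m2K", "T_inf_K", "sigma_scale", "drive_mode")
                for key in entry:
                    if key not in allowed:
                        raise ConfigError(f"unknown key scenarios[{k}].{key}")
                scenarios.append(
                    ScenarioSpec(
                        name=str(entry.get("name", f"S{k + 1}")),
                        U=_number(entry, f"scenarios[{k}]", "U_W_m2K", 0.0, nonneg=True),
                        T_inf=_number(
                            entry, f"scenarios[{k}]", "T_inf_K", 286.15, positive=True
                        ),
                        sigma_scale=_number(
                            entry, f"scenarios[{k}]", "sigma_scale", 1.0, positive=True
                        ),
                        drive_mode=str(entry.get("drive_mode", "constant_voltage")),
                    )
                )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfiguration(
        process=process, kinetics=kinetics, table=table, scenarios=scenarios
    )


def load_config(path: "str | Path | None") -> RunConfiguration:
    """Load, validate and default-fill a YAML configuration file.

    ``path=None`` yields the all-defaults configuration.
    """
    if path is None:
        return parse_config({})
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return parse_config(data)
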