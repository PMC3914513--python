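"""Shared fixtures: the expensive coupled runs are session-scoped."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from ohmicpast import (
    KineticsParams,
    ProcessConfig,
    PropertyTable,
    ThermalBC,
    builtin_cases,
    compare_drive_modes,
    run_simulation,
    run_suite,
)


@pytest.fixture(scope="session")
def table() -> PropertyTable:
    return PropertyTable.mashed_potato()


@pytest.fixture(scope="session")
def kinetics() -> KineticsParams:
    return KineticsParams()


@pytest.fixture(scope="session")
def base_config() -> ProcessConfig:
    """Default baseline process: 100 V, insulated, 150 s, 16x16, dt=0.5 s."""
    return ProcessConfig()


def make_constant_table(lam=0.5, vhc=3.4e6, sigma=2.0) -> PropertyTable:
    """Property table that is constant in temperature (two equal rows)."""
    return PropertyTable(
        temperatures_c=np.array([-100.0, 300.0]),
        thermal_conductivity=np.array([lam, lam]),
        volumetric_heat_capacity=np.array([vhc, vhc]),
        electrical_conductivity=np.array([sigma, sigma]),
    )


@pytest.fixture(scope="session")
def insulated_trace(base_config, table, kinetics):
    """Constant-voltage insulated 150-s run on the default grid."""
    return run_simulation(base_config, table, kinetics)


@pytest.fixture(scope="session")
def suite_results(base_config, kinetics):
    """The seven built-in sensitivity cases, each run to the 12D target."""
    return run_suite(builtin_cases(), base_config, kinetics)


@pytest.fixture(scope="session")
def drive_traces(base_config, table, kinetics):
    """Matched-energy constant-voltage vs constant-power insulated runs."""
    return compare_drive_modes(base_config, table, kinetics)


@pytest.fixture(scope="session")
def boundary_traces(base_config, table, kinetics):
    """150-s runs with exterior losses into cold and warm surroundings."""
    cold = replace(base_config, thermal_bc=ThermalBC(U=5.0, T_inf=286.15))
    warm = replace(base_config, thermal_bc=ThermalBC(U=5.0, T_inf=314.15))
    return {
        "cold": run_simulation(cold, table, kinetics),
        "warm": run_simulation(warm, table, kinetics),
    }
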