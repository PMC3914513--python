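"""Potential solver and Joule source: closed forms, conservation, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohmicpast import (
    CylinderGeometry,
    ElectricBC,
    build_mesh,
    electrode_current,
    joule_source,
    solve_potential,
    total_power,
)


def two_layer_profile(z, L, V0, sigma_bottom, sigma_top):
    """Series-resistor closed form: piecewise-linear potential."""
    V_mid = V0 * sigma_top / (sigma_bottom + sigma_top)
    return np.where(
        z < L / 2,
        V_mid * z / (L / 2),
        V_mid + (V0 - V_mid) * (z - L / 2) / (L / 2),
    )


def brute_force_1d_potential(z_eval, L, V0, sigma_of_z, n_nodes=4001):
    """Independent node-based 1D finite-difference solve of (σ V')' = 0."""
    z = np.linspace(0.0, L, n_nodes)
    h = z[1] - z[0]
    sig_mid = sigma_of_z(0.5 * (z[:-1] + z[1:]))
    A = np.zeros((n_nodes, n_nodes))
    b = np.zeros(n_nodes)
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    b[-1] = V0
    for k in range(1, n_nodes - 1):
        A[k, k - 1] = -sig_mid[k - 1]
        A[k, k] = sig_mid[k - 1] + sig_mid[k]
        A[k, k + 1] = -sig_mid[k]
    V = np.linalg.solve(A, b)
    return np.interp(z_eval, z, V)


@pytest.fixture()
def mesh():
    return build_mesh(CylinderGeometry(radius=0.02, length=0.06), 6, 8)


def test_uniform_conductivity_gives_linear_potential(mesh):
    V0 = 100.0
    sigma = np.full((mesh.nr, mesh.nz), 2.5)
    V = solve_potential(mesh, sigma, ElectricBC(V0))
    expected = V0 * mesh.z / mesh.geometry.length
    assert np.allclose(V, expected[None, :], atol=1e-9 * V0)


def test_potential_invariant_under_uniform_sigma_scaling(mesh):
    sigma = np.full((mesh.nr, mesh.nz), 1.3)
    bc = ElectricBC(50.0)
    V1 = solve_potential(mesh, sigma, bc)
    V2 = solve_potential(mesh, 2.0 * sigma, bc)
    assert np.allclose(V1, V2, atol=1e-10 * 50.0)


@pytest.mark.parametrize("nz", [8, 16])
def test_two_layer_matches_series_resistor_closed_form(nz):
    L, V0, s1 = 0.06, 100.0, 1.0
    mesh = build_mesh(CylinderGeometry(0.02, L), 4, nz)
    sigma = np.where(mesh.z[None, :] < L / 2, s1, 2.0 * s1) * np.ones((4, nz))
    V = solve_potential(mesh, sigma, ElectricBC(V0))
    expected = two_layer_profile(mesh.z, L, V0, s1, 2.0 * s1)
    assert np.allclose(V, expected[None, :], atol=1e-8 * V0)
    # flux-consistent interface reconstruction gives the (2/3)·V0 mid-plane value
    v_mid = (s1 * V[0, nz // 2 - 1] + 2.0 * s1 * V[0, nz // 2]) / (3.0 * s1)
    assert v_mid == pytest.approx(2.0 / 3.0 * V0, rel=1e-9)


def test_two_layer_agrees_with_brute_force_1d_solver():
    L, V0 = 0.06, 100.0
    mesh = build_mesh(CylinderGeometry(0.02, L), 3, 12)
    sigma = np.where(mesh.z[None, :] < L / 2, 1.0, 2.0) * np.ones((3, 12))
    V = solve_potential(mesh, sigma, ElectricBC(V0))
    oracle = brute_force_1d_potential(
        mesh.z, L, V0, lambda z: np.where(z < L / 2, 1.0, 2.0)
    )
    assert np.allclose(V[0, :], oracle, atol=1e-6 * V0)


def test_two_layer_error_decreases_under_refinement():
    L, V0 = 0.06, 100.0

    def midplane_error(nz):
        mesh = build_mesh(CylinderGeometry(0.02, L), 4, nz)
        # interface offset from a face so the discrete solution is inexact
        sigma = np.where(mesh.z[None, :] < 0.45 * L, 1.0, 3.0) * np.ones((4, nz))
        V = solve_potential(mesh, sigma, ElectricBC(V0))
        exact = brute_force_1d_potential(
            mesh.z, L, V0, lambda z: np.where(z < 0.45 * L, 1.0, 3.0)
        )
        return float(np.max(np.abs(V[0, :] - exact)))

    assert midplane_error(64) < midplane_error(8)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_maximum_principle_and_conservation_for_random_sigma(seed):
    """0 ≤ V ≤ V0, equal electrode currents, and power = V·I."""
    rng = np.random.default_rng(seed)
    mesh = build_mesh(CylinderGeometry(0.02, 0.05), 5, 6)
    sigma = rng.uniform(0.5, 5.0, size=(5, 6))
    V0 = 80.0
    V = solve_potential(mesh, sigma, ElectricBC(V0))
    assert np.all(V >= -1e-9 * V0) and np.all(V <= V0 * (1 + 1e-9))

    I_top = electrode_current(mesh, sigma, V, V0, "electrode_top")
    I_bot = electrode_current(mesh, sigma, V, V0, "electrode_bottom")
    assert I_top == pytest.approx(I_bot, rel=1e-8)

    Q = joule_source(mesh, sigma, V, V0)
    assert np.all(Q >= 0.0)
    assert total_power(mesh, Q) == pytest.approx(V0 * I_top, rel=1e-8)


def test_joule_source_uniform_closed_form():
    # uniform σ between plates: Q = σ (V0/L)² everywhere
    L, V0, sig = 0.03, 100.0, 1.228
    mesh = build_mesh(CylinderGeometry(0.01, L), 4, 10)
    sigma = np.full((4, 10), sig)
    V = solve_potential(mesh, sigma, ElectricBC(V0))
    Q = joule_source(mesh, sigma, V, V0)
    assert np.allclose(Q, sig * (V0 / L) ** 2, rtol=1e-9)
    assert Q[0, 0] == pytest.approx(1.364e7, rel=1e-3)


def test_zero_voltage_means_zero_source(mesh):
    sigma = np.full((mesh.nr, mesh.nz), 2.0)
    Q = joule_source(mesh, sigma, np.zeros((mesh.nr, mesh.nz)), 0.0)
    assert np.all(Q == 0.0)


def test_source_invariant_under_electrode_swap(mesh):
    """Swapping which electrode is grounded (mirroring the cell in z)
    leaves |∇V| and hence Q unchanged."""
    rng = np.random.default_rng(7)
    sigma = rng.uniform(1.0, 3.0, size=(mesh.nr, mesh.nz))
    V0 = 60.0
    V = solve_potential(mesh, sigma, ElectricBC(V0))
    Q1 = joule_source(mesh, sigma, V, V0)
    V_sw = solve_potential(mesh, sigma[:, ::-1], ElectricBC(V0))
    Q2 = joule_source(mesh, sigma[:, ::-1], V_sw, V0)
    assert np.allclose(Q1, Q2[:, ::-1], rtol=1e-9)
    # and the mirrored potential is the complement of the original
    assert np.allclose(V_sw[:, ::-1], V0 - V, atol=1e-9 * V0)


def test_total_power_closed_form_and_voltage_scaling():
    mesh = build_mesh(CylinderGeometry(0.025, 0.05), 8, 8)
    Q = np.full((8, 8), 1.0e6)
    assert total_power(mesh, Q) == pytest.approx(98.17, abs=0.01)

    sigma = np.full((8, 8), 2.0)
    powers = []
    for V0 in (100.0, 50.0):
        V = solve_potential(mesh, sigma, ElectricBC(V0))
        powers.append(total_power(mesh, joule_source(mesh, sigma, V, V0)))
    assert powers[1] == pytest.approx(powers[0] / 4.0, rel=1e-10)


def test_degenerate_sigma_rejected(mesh):
    with pytest.raises(ValueError):
        solve_potential(mesh, np.zeros((mesh.nr, mesh.nz)), ElectricBC(10.0))
    with pytest.raises(ValueError):
        ElectricBC(-5.0)
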