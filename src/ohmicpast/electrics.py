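"""Quasistatic electrical potential and Joule heat source.

The potential obeys ``∇·σ∇V = 0`` with the applied voltage imposed on one
electrode, ground on the other, and electrical insulation on the lateral
surface.  Because the thermal transient is slow compared with any electrical
time scale, the potential re-equilibrates instantaneously as σ(T) evolves
(quasistatic approximation).  The volumetric heat source is Joule's law,
``Q = σ |∇V|²``.

Discretely, ``Q`` is assembled from per-face dissipations
``G_f (ΔV_f)²`` split evenly between the two adjacent cells (boundary faces
assign fully to their one cell).  This makes the global energy identity
``Σ Q·vol = V_applied · I_electrode`` hold to linear-solver precision for
arbitrary positive σ fields, and reduces to the exact ``σ (V/L)²`` for a
uniform conductivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fv import diffusion_operator, face_conductances
from .mesh import AxisymMesh

DRIVE_MODES = ("constant_voltage", "constant_power")


@dataclass(frozen=True)
class ElectricBC:
    """Electrode drive: potential difference [V] and drive mode."""

    applied_voltage: float
    drive_mode: str = "constant_voltage"

    def __post_init__(self) -> None:
        if self.applied_voltage <= 0.0:
            raise ValueError("applied_voltage must be positive")
        if self.drive_mode not in DRIVE_MODES:
            raise ValueError(
                f"drive_mode must be one of {DRIVE_MODES}, got {self.drive_mode!r}"
            )


def _electrode_conductances(
    mesh: AxisymMesh, sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Half-cell Dirichlet conductances at bottom (j=0) and top (j=nz-1)."""
    half = mesh.axial_face_areas / (0.5 * mesh.dz)
    return sigma[:, 0] * half, sigma[:, -1] * half


def solve_potential(
    mesh: AxisymMesh, sigma: np.ndarray, bc: ElectricBC
) -> np.ndarray:
    """Solve ``∇·σ∇V = 0`` for the cell-centered potential [V].

    Dirichlet ``V = applied_voltage`` on the top electrode, ``V = 0`` on the
    bottom electrode, zero normal current on the lateral surface and the
    axis.  Direct sparse solve of the SPD system.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (mesh.nr, mesh.nz):
        raise ValueError("sigma field does not match mesh")
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0.0):
        raise ValueError("sigma must be finite and strictly positive")

    Gr, Gz = face_conductances(mesh, sigma)
    A = diffusion_operator(mesh, Gr, Gz)
    Gb, Gt = _electrode_conductances(mesh, sigma)

    bdiag = np.zeros((mesh.nr, mesh.nz))
    bdiag[:, 0] += Gb  # bottom electrode, V = 0: no rhs contribution
    bdiag[:, -1] += Gt
    rhs = np.zeros((mesh.nr, mesh.nz))
    rhs[:, -1] = Gt * bc.applied_voltage

    M = (A + sp.diags(bdiag.ravel())).tocsc()
    V = spla.spsolve(M, rhs.ravel())
    if not np.all(np.isfinite(V)):
        raise ArithmeticError(
            "potential solve produced non-finite values "
            "(degenerate conductivity or broken boundary tags?)"
        )
    return V.reshape(mesh.nr, mesh.nz)


def joule_source(
    mesh: AxisymMesh, sigma: np.ndarray, V: np.ndarray, applied_voltage: float
) -> np.ndarray:
    """Per-cell Joule source ``Q = σ|∇V|²`` [W m⁻³].

    Assembled from face dissipations (half to each neighbour, boundary faces
    fully to their cell) so that ``total_power`` equals the electrode power
    ``V·I`` identically.
    """
    V = np.asarray(V, dtype=float)
    if V.shape != (mesh.nr, mesh.nz):
        raise ValueError("potential field does not match mesh")
    Gr, Gz = face_conductances(mesh, sigma)
    Dr = Gr * (V[1:, :] - V[:-1, :]) ** 2
    Dz = Gz * (V[:, 1:] - V[:, :-1]) ** 2
    Gb, Gt = _electrode_conductances(mesh, sigma)
    Db = Gb * (V[:, 0] - 0.0) ** 2
    Dt = Gt * (applied_voltage - V[:, -1]) ** 2

    P = np.zeros((mesh.nr, mesh.nz))
    P[:-1, :] += 0.5 * Dr
    P[1:, :] += 0.5 * Dr
    P[:, :-1] += 0.5 * Dz
    P[:, 1:] += 0.5 * Dz
    P[:, 0] += Db
    P[:, -1] += Dt
    return P / mesh.cell_volumes


def electrode_current(
    mesh: AxisymMesh,
    sigma: np.ndarray,
    V: np.ndarray,
    applied_voltage: float,
    electrode: str = "electrode_top",
) -> float:
    """Total current [A] entering through one electrode."""
    Gb, Gt = _electrode_conductances(mesh, sigma)
    if electrode == "electrode_top":
        return float(np.sum(Gt * (applied_voltage - V[:, -1])))
    if electrode == "electrode_bottom":
        return float(np.sum(Gb * (V[:, 0] - 0.0)))
    raise KeyError(f"unknown electrode {electrode!r}")


def total_power(mesh: AxisymMesh, Q: np.ndarray) -> float:
    """Volume integral of the heat source, W."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (mesh.nr, mesh.nz):
        raise ValueError("source field does not match mesh")
    return float(np.sum(Q * mesh.cell_volumes))
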