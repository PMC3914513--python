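"""Transient heat conduction with Joule source and convective losses.

Advances ``VHC · ∂T/∂t = ∇·λ∇T + Q`` by one backward-Euler step at a time.
Exterior faces are either perfectly insulated or lose heat by Newton
cooling, ``q = U (T_surface − T_inf)``, where the overall coefficient ``U``
lumps every composite resistance between the sample surface and the
surroundings.  Discretely the Robin closure uses the series combination of
``U`` with the half-cell conduction resistance, ``h = 1/(1/U + d/(2λ))``,
so the flux is evaluated at the face rather than the cell center; for the
``U`` of a few W m⁻² K⁻¹ relevant here the correction is tiny.

Properties are supplied by the caller frozen at the step's start
temperature (lagged-coefficient linearization); the step itself is then a
single symmetric positive-definite sparse solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fv import diffusion_operator, face_conductances
from .mesh import AxisymMesh

#: Temperature above which the model (and the property tables) are invalid.
BOILING_GUARD_K = 373.15


@dataclass(frozen=True)
class ThermalBC:
    """Convective-loss boundary: ``U`` [W m⁻² K⁻¹], ``T_inf`` [K], per-face flags.

    ``U = 0`` (or a disabled flag) means a perfectly insulated face.
    By default losses act on all exterior faces — both electrode ends and
    the lateral surface.
    """

    U: float = 0.0
    T_inf: float = 286.15
    electrode_bottom: bool = True
    electrode_top: bool = True
    lateral: bool = True

    def __post_init__(self) -> None:
        if self.U < 0.0:
            raise ValueError("U must be nonnegative")


def _robin_coefficients(
    mesh: AxisymMesh, lam: np.ndarray, bc: ThermalBC
) -> np.ndarray:
    """Per-cell Robin conductances h_eff·A [W K⁻¹], shape (nr, nz).

    Sums the contributions of every enabled exterior face of each cell
    (corner cells of the outer ring get both an electrode and a lateral
    term).
    """
    HA = np.zeros((mesh.nr, mesh.nz))
    if bc.U <= 0.0:
        return HA
    if bc.electrode_bottom:
        h = 1.0 / (1.0 / bc.U + 0.5 * mesh.dz / lam[:, 0])
        HA[:, 0] += h * mesh.axial_face_areas
    if bc.electrode_top:
        h = 1.0 / (1.0 / bc.U + 0.5 * mesh.dz / lam[:, -1])
        HA[:, -1] += h * mesh.axial_face_areas
    if bc.lateral:
        h = 1.0 / (1.0 / bc.U + 0.5 * mesh.dr / lam[-1, :])
        HA[-1, :] += h * mesh.lateral_face_area_per_cell
    return HA


def step_temperature(
    mesh: AxisymMesh,
    T: np.ndarray,
    Q: np.ndarray,
    lam: np.ndarray,
    vhc: np.ndarray,
    bc: ThermalBC,
    dt: float,
) -> np.ndarray:
    """One implicit (backward-Euler) step of the heat equation.

    Parameters are per-cell fields on ``mesh``: current temperature ``T``
    [K], heat source ``Q`` [W m⁻³], thermal conductivity ``lam`` and
    volumetric heat capacity ``vhc`` (typically evaluated at ``T``).
    Returns the temperature at ``t + dt``.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    for name, f in (("T", T), ("Q", Q), ("lam", lam), ("vhc", vhc)):
        if np.shape(f) != (mesh.nr, mesh.nz):
            raise ValueError(f"{name} field does not match mesh")

    Gr, Gz = face_conductances(mesh, lam)
    A = diffusion_operator(mesh, Gr, Gz)
    cap = (vhc * mesh.cell_volumes / dt).ravel()
    HA = _robin_coefficients(mesh, lam, bc)

    M = A + sp.diags(cap + HA.ravel())
    rhs = cap * T.ravel() + (Q * mesh.cell_volumes).ravel() + HA.ravel() * bc.T_inf
    T_new = spla.spsolve(M.tocsc(), rhs)
    if not np.all(np.isfinite(T_new)):
        raise ArithmeticError("thermal step produced non-finite temperatures")
    return T_new.reshape(mesh.nr, mesh.nz)


def energy_audit(
    mesh: AxisymMesh,
    T_before: np.ndarray,
    T_after: np.ndarray,
    Q: np.ndarray,
    lam: np.ndarray,
    vhc: np.ndarray,
    bc: ThermalBC,
    dt: float,
) -> float:
    """Residual [W] of the discrete energy balance of one implicit step.

    ``|dE/dt − (source − boundary losses)|`` with the loss evaluated, like
    the implicit step itself, at the end-of-step temperature.  For
    property fields held constant over the step the balance is exact up to
    linear-solver round-off.
    """
    stored = float(np.sum(vhc * mesh.cell_volumes * (T_after - T_before))) / dt
    source = float(np.sum(Q * mesh.cell_volumes))
    HA = _robin_coefficients(mesh, lam, bc)
    losses = float(np.sum(HA * (T_after - bc.T_inf)))
    return abs(stored - (source - losses))
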