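"""Shared finite-volume assembly helpers (internal).

Both the potential and the heat equation discretize ``∇·k∇u`` on the same
axisymmetric grid; this module builds the face conductances [W K⁻¹ or S]
and the sparse diffusion operator they induce.  Face coefficients use the
harmonic mean of the adjacent cell values, which preserves flux continuity
across property jumps.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .mesh import AxisymMesh


def harmonic_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def face_conductances(mesh: AxisymMesh, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior-face conductances ``G = k_face · A_face / d``.

    Returns ``(Gr, Gz)`` with shapes ``(nr-1, nz)`` (radial faces between
    rings i and i+1) and ``(nr, nz-1)`` (axial faces between layers j and
    j+1).  Axis and exterior faces are not included (zero-flux by default).
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (mesh.nr, mesh.nz):
        raise ValueError(f"field shape {k.shape} does not match mesh ({mesh.nr}, {mesh.nz})")
    kr = harmonic_mean(k[:-1, :], k[1:, :])
    Gr = kr * mesh.radial_face_areas[1:-1, None] / mesh.dr
    kz = harmonic_mean(k[:, :-1], k[:, 1:])
    Gz = kz * mesh.axial_face_areas[:, None] / mesh.dz
    return Gr, Gz


def diffusion_operator(mesh: AxisymMesh, Gr: np.ndarray, Gz: np.ndarray) -> sp.csr_matrix:
    """Sparse SPD operator ``A`` with ``(A u)_c = Σ_faces G (u_c − u_nb)``.

    Cells are flattened C-order, index ``i*nz + j``.  Only interior faces
    enter; Dirichlet/Robin closures are added by the callers on the diagonal.
    """
    n = mesh.n_cells
    nz = mesh.nz
    diag = np.zeros((mesh.nr, mesh.nz))
    diag[:-1, :] += Gr
    diag[1:, :] += Gr
    diag[:, :-1] += Gz
    diag[:, 1:] += Gz

    # radial couplings: cell (i, j) <-> (i+1, j), flat offset nz
    rows_r = (np.arange(mesh.nr - 1)[:, None] * nz + np.arange(nz)[None, :]).ravel()
    # axial couplings: cell (i, j) <-> (i, j+1), flat offset 1
    rows_z = (np.arange(mesh.nr)[:, None] * nz + np.arange(nz - 1)[None, :]).ravel()

    A = sp.coo_matrix(
        (
            np.concatenate(
                [diag.ravel(), -Gr.ravel(), -Gr.ravel(), -Gz.ravel(), -Gz.ravel()]
            ),
            (
                np.concatenate([np.arange(n), rows_r, rows_r + nz, rows_z, rows_z + 1]),
                np.concatenate([np.arange(n), rows_r + nz, rows_r, rows_z + 1, rows_z]),
            ),
        ),
        shape=(n, n),
    )
    return A.tocsr()
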