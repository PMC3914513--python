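"""Axisymmetric structured finite-volume mesh of a solid cylinder.

The sample is a homogeneous cylinder heated between two end electrodes, so
geometry, loading and boundary conditions are all rotationally symmetric and
the continuous fields depend only on (r, z).  The mesh is a uniform
cell-centered grid of ``nr × nz`` annular cells; scalar fields live on cells
as ``(nr, nz)`` arrays.

Boundary faces are tagged implicitly by position: ``z = 0`` is the bottom
electrode, ``z = L`` the top electrode, and ``r = R`` the lateral surface.
The axis ``r = 0`` is a symmetry line carrying zero radial-face area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Names of the exterior boundary families.
BOUNDARY_TAGS = ("electrode_bottom", "electrode_top", "lateral")


@dataclass(frozen=True)
class CylinderGeometry:
    """Cylindrical sample: ``radius`` [m] and electrode gap ``length`` [m]."""

    radius: float
    length: float

    def __post_init__(self) -> None:
        if not (self.radius > 0.0 and self.length > 0.0):
            raise ValueError("radius and length must be positive")

    @property
    def volume(self) -> float:
        """π R² L, m³."""
        return np.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class AxisymMesh:
    """Uniform cell-centered (r, z) grid over a :class:`CylinderGeometry`.

    Attributes
    ----------
    r, z
        Cell-center coordinates, shape ``(nr,)`` / ``(nz,)``.
    cell_volumes
        Annular cell volumes ``2π r Δr Δz``, shape ``(nr, nz)``.
    radial_face_areas
        Areas of the cylindrical faces at radii ``i·Δr``, shape ``(nr+1,)``
        per unit axial cell (already times Δz); index 0 (the axis) is zero.
    axial_face_areas
        Annular end-face areas ``2π r Δr`` per radial ring, shape ``(nr,)``.
    """

    geometry: CylinderGeometry
    nr: int
    nz: int
    dr: float = field(init=False)
    dz: float = field(init=False)
    r: np.ndarray = field(init=False, repr=False)
    z: np.ndarray = field(init=False, repr=False)
    cell_volumes: np.ndarray = field(init=False, repr=False)
    radial_face_areas: np.ndarray = field(init=False, repr=False)
    axial_face_areas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.nr < 2 or self.nz < 2:
            raise ValueError("need at least 2 cells in each direction")
        R, L = self.geometry.radius, self.geometry.length
        dr = R / self.nr
        dz = L / self.nz
        r = (np.arange(self.nr) + 0.5) * dr
        z = (np.arange(self.nz) + 0.5) * dz
        object.__setattr__(self, "dr", dr)
        object.__setattr__(self, "dz", dz)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "z", z)
        object.__setattr__(
            self,
            "cell_volumes",
            np.broadcast_to((2.0 * np.pi * r * dr * dz)[:, None], (self.nr, self.nz)).copy(),
        )
        object.__setattr__(
            self,
            "radial_face_areas",
            2.0 * np.pi * (np.arange(self.nr + 1) * dr) * dz,
        )
        object.__setattr__(self, "axial_face_areas", 2.0 * np.pi * r * dr)

    @property
    def n_cells(self) -> int:
        return self.nr * self.nz

    @property
    def lateral_face_area_per_cell(self) -> float:
        """Exterior lateral band area of one outer-ring cell, 2π R Δz."""
        return 2.0 * np.pi * self.geometry.radius * self.dz

    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())

    def boundary_cells(self, tag: str) -> np.ndarray:
        """(i, j) index pairs of cells whose exterior face carries ``tag``."""
        if tag == "electrode_bottom":
            return np.array([(i, 0) for i in range(self.nr)])
        if tag == "electrode_top":
            return np.array([(i, self.nz - 1) for i in range(self.nr)])
        if tag == "lateral":
            return np.array([(self.nr - 1, j) for j in range(self.nz)])
        raise KeyError(f"unknown boundary tag {tag!r}; expected one of {BOUNDARY_TAGS}")

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Node (face) coordinates, shapes (nr+1,), (nz+1,); for writers."""
        return (
            np.arange(self.nr + 1) * self.dr,
            np.arange(self.nz + 1) * self.dz,
        )


def build_mesh(geom: CylinderGeometry, nr: int, nz: int) -> AxisymMesh:
    """Build a uniform axisymmetric mesh with ``nr × nz`` cells."""
    return AxisymMesh(geometry=geom, nr=int(nr), nz=int(nz))
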