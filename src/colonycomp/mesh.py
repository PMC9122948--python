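"""Triangulated disk geometry.

The spatial domain is a two-dimensional disk of radius ``R`` (the growth
medium) with a concentric inoculum footprint of radius ``R0`` in which
founder microcolonies are placed.  The disk is triangulated by a
deterministic hexagonal-lattice construction: interior nodes on a regular
triangular lattice whose spacing is chosen to hit a target element area,
plus equally spaced boundary nodes on the outer circle, connected by a
Delaunay triangulation.  All lengths are nondimensional (one space unit is
roughly 0.15 mm in the motivating assay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay


class MeshError(ValueError):
    """Raised for infeasible or inconsistent mesh requests."""


@dataclass(frozen=True)
class DomainGeometry:
    """Disk domain of radius ``R`` with inoculum footprint of radius ``R0``.

    ``target_element_area`` controls mesh resolution (nondimensional
    length squared).  Defaults give an inoculum region holding >= 824
    mesh nodes, the largest founder density studied, while keeping the
    colony front inside the domain up to the default end time.
    """

    R: float = 72.0
    R0: float = 14.0
    target_element_area: float = 0.36

    def __post_init__(self) -> None:
        if not (0 < self.R0 < self.R):
            raise MeshError(f"require 0 < R0 < R, got R0={self.R0}, R={self.R}")
        if self.target_element_area <= 0:
            raise MeshError("target_element_area must be positive")

    @property
    def spacing(self) -> float:
        """Lattice spacing of an equilateral triangle with the target area."""
        return float(np.sqrt(4.0 * self.target_element_area / np.sqrt(3.0)))


@dataclass
class TriangularMesh:
    """Conforming triangulation of the disk.

    ``node_coords`` is ``(n_nodes, 2)``; ``triangles`` is ``(n_tri, 3)``
    (indices into nodes); ``inoculum_node_ids`` are the nodes strictly
    inside radius ``R0``.
    """

    geometry: DomainGeometry
    node_coords: np.ndarray
    triangles: np.ndarray
    inoculum_node_ids: np.ndarray
    _fem: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def node_radii(self) -> np.ndarray:
        return np.hypot(self.node_coords[:, 0], self.node_coords[:, 1])

    def triangle_areas(self) -> np.ndarray:
        p = self.node_coords[self.triangles]
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])

    @property
    def fem(self) -> dict:
        """Cached P1 finite-element arrays (element stiffness, lumped mass)."""
        if not self._fem:
            self._fem.update(_p1_assembly(self.node_coords, self.triangles))
        return self._fem


def _p1_assembly(nodes: np.ndarray, tris: np.ndarray) -> dict:
    p = nodes[tris]  # (ne, 3, 2)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    area = 0.5 * np.abs(det)
    x, y = p[:, :, 0], p[:, :, 1]
    # gradients of the linear basis functions on each element
    gx = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], 1) / det[:, None]
    gy = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], 1) / det[:, None]
    stiff = area[:, None, None] * (gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :])
    lumped = np.zeros(len(nodes))
    np.add.at(lumped, tris.ravel(), np.repeat(area / 3.0, 3))
    kdiag = np.zeros(len(nodes))
    np.add.at(kdiag, tris.ravel(), np.einsum("eii->ei", stiff).ravel())
    return {"stiff": stiff, "lumped_mass": lumped, "kdiag": kdiag, "areas": area}


def build_disk_mesh(geometry: DomainGeometry) -> TriangularMesh:
    """Triangulate the disk of radius ``geometry.R``.

    Interior nodes lie on a hexagonal lattice with spacing derived from
    ``target_element_area``; the boundary is an equally spaced polygon on
    the outer circle.  The construction is deterministic: the same
    geometry always yields the same mesh.

    Raises
    ------
    MeshError
        If the requested element area is too coarse to resolve the disk.
    """
    R, h = geometry.R, geometry.spacing
    if h >= R:
        raise MeshError(
            f"target_element_area={geometry.target_element_area} implies spacing "
            f"{h:.3g} >= disk radius {R}; request a finer mesh"
        )
    dy = h * np.sqrt(3.0) / 2.0
    nrow = int(np.ceil(R / dy)) + 1
    ncol = int(np.ceil(R / h)) + 1
    rows = []
    for j in range(-nrow, nrow + 1):
        xs = (np.arange(-ncol, ncol + 1) + (0.5 if j % 2 else 0.0)) * h
        rows.append(np.column_stack([xs, np.full_like(xs, j * dy)]))
    lattice = np.concatenate(rows)
    rad = np.hypot(lattice[:, 0], lattice[:, 1])
    interior = lattice[rad <= R - 0.6 * h]

    n_bnd = int(np.ceil(2.0 * np.pi * R / h))
    theta = np.linspace(0.0, 2.0 * np.pi, n_bnd, endpoint=False)
    boundary = np.column_stack([R * np.cos(theta), R * np.sin(theta)])

    nodes = np.vstack([interior, boundary])
    tri = Delaunay(nodes)
    mesh = TriangularMesh(
        geometry=geometry,
        node_coords=nodes,
        triangles=tri.simplices,
        inoculum_node_ids=np.flatnonzero(np.hypot(nodes[:, 0], nodes[:, 1]) < geometry.R0),
    )
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        raise MeshError("degenerate triangle produced")  # pragma: no cover
    return mesh
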