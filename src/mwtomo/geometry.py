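"""Grids, imaging zones and antenna arrays for 2D tomographic imaging.

All coordinates are continuous and in metres, centered on the origin.
Grid indices are 0-based; node ``(i, j)`` of an ``n``-cell grid sits at
``((i - n/2) h, (j - n/2) h)`` for ``i, j in 0..n``.  Angles are measured
from the +x axis, counter-clockwise positive; the clockwise antenna
numbering convention of circular tomography arrays (antenna #1 at the
bottom of the circle) is expressed on top of that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UniformGrid",
    "ImagingZone",
    "AntennaArray",
    "build_grid",
    "select_imaging_zone",
    "node_cell_adjacency",
    "build_antenna_array",
]


@dataclass(frozen=True)
class UniformGrid:
    """Uniform square grid of cells centered on the origin.

    Parameters
    ----------
    side_length : float
        Physical side of the square domain (m).
    n_cells_per_side : int
        Number of cells along one side; the grid has
        ``(n_cells_per_side + 1)**2`` nodes at cell corners.
    """

    side_length: float
    n_cells_per_side: int

    def __post_init__(self) -> None:
        if not float(self.side_length) > 0:
            raise ValueError("side_length must be positive")
        n = self.n_cells_per_side
        if not (isinstance(n, (int, np.integer)) and not isinstance(n, bool)):
            raise TypeError("n_cells_per_side must be an integer")
        if n < 2:
            raise ValueError("n_cells_per_side must be >= 2")

    @property
    def h(self) -> float:
        """Cell size (m)."""
        return self.side_length / self.n_cells_per_side

    @property
    def n_nodes_per_side(self) -> int:
        return self.n_cells_per_side + 1

    @property
    def n_nodes(self) -> int:
        return self.n_nodes_per_side**2

    def node_coordinates(self, ij: np.ndarray) -> np.ndarray:
        """Coordinates (m) of nodes given as an ``(m, 2)`` index array."""
        ij = np.asarray(ij)
        return (ij - self.n_cells_per_side / 2.0) * self.h

    def cell_centers(self, ij: np.ndarray) -> np.ndarray:
        """Coordinates (m) of cell centers given an ``(m, 2)`` index array."""
        ij = np.asarray(ij)
        return (ij + 0.5 - self.n_cells_per_side / 2.0) * self.h


def build_grid(side_length: float, n_cells_per_side: int) -> UniformGrid:
    """Build the uniform forward/parameter grid."""
    return UniformGrid(float(side_length), n_cells_per_side)


@dataclass
class ImagingZone:
    """Step-wise circular subset of grid cells carrying the unknowns.

    The unknowns live on the distinct corner nodes of the selected cells,
    ordered row-major over the full grid.  ``node_area[t]`` is the summed
    area of in-zone cells incident to node ``t`` (the quantity ``A`` of the
    nodal-adjoint constant); ``M = 4`` is the vertex count of a square cell.
    """

    grid: UniformGrid
    zone_radius: float
    cell_ij: np.ndarray  # (n_cells, 2) int
    node_ij: np.ndarray  # (n_nodes, 2) int, row-major order
    node_area: np.ndarray  # (n_nodes,) float, A_tau in m^2
    M: int = 4
    _node_pos: dict = field(default_factory=dict, repr=False)
    _cell_set: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        self._node_pos = {
            (int(i), int(j)): t for t, (i, j) in enumerate(self.node_ij)
        }
        self._cell_set = {(int(i), int(j)) for i, j in self.cell_ij}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ij)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ij)

    @property
    def node_coords(self) -> np.ndarray:
        return self.grid.node_coordinates(self.node_ij)

    @property
    def effective_diameter(self) -> float:
        """Diameter (m) of the circle with the same area as the cell union."""
        area = self.n_cells * self.grid.h**2
        return 2.0 * np.sqrt(area / np.pi)

    def node_position(self, ij) -> int:
        """Position of grid node ``(i, j)`` in the unknown ordering."""
        key = (int(ij[0]), int(ij[1]))
        if key not in self._node_pos:
            raise ValueError(f"node {key} is not in the imaging zone")
        return self._node_pos[key]

    def contains_cell(self, ij) -> bool:
        return (int(ij[0]), int(ij[1])) in self._cell_set

    def boundary_edge_count(self) -> int:
        """Number of cell edges on the boundary of the cell union."""
        count = 0
        for i, j in self.cell_ij:
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if (int(i) + di, int(j) + dj) not in self._cell_set:
                    count += 1
        return count

    def cell_vertex_positions(self) -> np.ndarray:
        """(n_cells, 4) array: unknown-ordering positions of each cell's corners."""
        out = np.empty((self.n_cells, 4), dtype=np.intp)
        for c, (i, j) in enumerate(self.cell_ij):
            out[c] = [
                self._node_pos[(int(i), int(j))],
                self._node_pos[(int(i), int(j) + 1)],
                self._node_pos[(int(i) + 1, int(j))],
                self._node_pos[(int(i) + 1, int(j) + 1)],
            ]
        return out


def select_imaging_zone(grid: UniformGrid, zone_radius: float) -> ImagingZone:
    """Select the step-wise circular imaging zone.

    A cell is in-zone iff its *center* lies within ``zone_radius`` of the
    grid center.  The default configuration (25 cm / 64 cells / 69.8 mm)
    selects 1012 cells with 1085 distinct corner nodes.

    Raises
    ------
    ValueError
        If the radius is non-positive, reaches the domain boundary, or the
        selected cells touch the outermost cell ring (scatterers must be
        interior to the domain).
    """
    zone_radius = float(zone_radius)
    if not 0 < zone_radius < grid.side_length / 2:
        raise ValueError("zone_radius must lie in (0, side_length/2)")

    n = grid.n_cells_per_side
    idx = np.arange(n)
    ci, cj = np.meshgrid(idx, idx, indexing="ij")
    centers = grid.cell_centers(np.stack([ci.ravel(), cj.ravel()], axis=1))
    inside = np.hypot(centers[:, 0], centers[:, 1]) <= zone_radius
    cell_ij = np.stack([ci.ravel()[inside], cj.ravel()[inside]], axis=1)
    if cell_ij.size and (
        cell_ij.min() == 0 or cell_ij.max() == n - 1
    ):
        raise ValueError("imaging zone touches the domain boundary")

    # distinct corners, row-major (flat node index) order
    corners = np.concatenate(
        [cell_ij + [di, dj] for di in (0, 1) for dj in (0, 1)]
    ) if len(cell_ij) else np.empty((0, 2), dtype=int)
    if len(corners):
        flat = corners[:, 0] * (n + 1) + corners[:, 1]
        uniq = np.unique(flat)
        node_ij = np.stack([uniq // (n + 1), uniq % (n + 1)], axis=1)
    else:
        node_ij = np.empty((0, 2), dtype=int)

    # per-node area: h^2 per incident in-zone cell
    cell_set = {(int(i), int(j)) for i, j in cell_ij}
    h2 = grid.h**2
    node_area = np.zeros(len(node_ij))
    for t, (i, j) in enumerate(node_ij):
        i, j = int(i), int(j)
        incident = sum(
            (i + di, j + dj) in cell_set
            for di in (-1, 0)
            for dj in (-1, 0)
        )
        node_area[t] = incident * h2

    return ImagingZone(grid, zone_radius, cell_ij, node_ij, node_area)


def node_cell_adjacency(zone: ImagingZone, node) -> set:
    """In-zone cells incident to a node (the region Omega_tau).

    ``node`` is a grid node index pair ``(i, j)``.  Returns the set of
    in-zone cell index pairs touching the node (1-4 cells); the node's
    area weight is ``len(result) * h**2``.
    """
    i, j = int(node[0]), int(node[1])
    if (i, j) not in zone._node_pos:
        raise ValueError(f"node {(i, j)} is not in the imaging zone")
    return {
        (i + di, j + dj)
        for di in (-1, 0)
        for dj in (-1, 0)
        if zone.contains_cell((i + di, j + dj))
    }


@dataclass(frozen=True)
class AntennaArray:
    """Circular array of ideal 2D line sources / point receivers.

    Antenna #1 (index 0) sits at the bottom of the circle, at angle -90
    degrees; subsequent antennas follow clockwise.  ``amplitude`` is the
    equivalent line-current amplitude |J| shared by all antennas.
    """

    n_antennas: int
    diameter: float
    amplitude: float = 1.0
    positions: np.ndarray = field(default=None, repr=False)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def build_antenna_array(
    n: int,
    diameter: float,
    amplitude: float = 1.0,
    grid: UniformGrid | None = None,
    zone: ImagingZone | None = None,
) -> AntennaArray:
    """Place ``n`` antennas equally spaced on a circle of given diameter.

    If ``grid``/``zone`` are supplied, the circle is required to lie
    strictly outside the imaging zone and strictly inside the domain.
    """
    if n < 3:
        raise ValueError("need at least 3 antennas")
    diameter = float(diameter)
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if zone is not None and diameter / 2.0 <= zone.zone_radius:
        raise ValueError("antenna circle must enclose the imaging zone")
    if grid is not None and diameter >= grid.side_length:
        raise ValueError("antenna circle must lie inside the grid domain")

    k = np.arange(n)
    theta = np.deg2rad(-90.0) - 2.0 * np.pi * k / n  # clockwise from bottom
    r = diameter / 2.0
    positions = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return AntennaArray(n, diameter, float(amplitude), positions)
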