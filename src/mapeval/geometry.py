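"""Tissue geometries, electrode arrays and surface-projection diagnostics.

Coordinates are centimetres throughout; meshes and electrode arrays share a
single Cartesian frame.  Two desk-scale fixture geometries are provided: a
planar triangulated sheet (all nodes on the mapped surface, normals +z) and a
closed triangulated shell (watertight icosphere, outward normals).  Electrode
arrays model the three catheter types used for mapping-system evaluation:
8x8 basket arrays with good or poor wall contact and a 6x6 high-resolution
uniform grid.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TissueGeometry",
    "ElectrodeArray",
    "ProjectionStats",
    "build_sheet_geometry",
    "build_shell_geometry",
    "place_basket_array",
    "place_uniform_array",
    "surface_projection_stats",
]

# Ordered ring offsets (drow, dcol) starting at the "north" neighbour and
# proceeding clockwise when the array is viewed from outside the tissue along
# the surface normal.  Row index decreases toward "north".
_RING_OFFSETS = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass
class TissueGeometry:
    """A tissue mesh with an identified mapped (endocardial) surface.

    Parameters
    ----------
    nodes : (N, 3) float array, cm
    elements : (E, k) int array
        Simplices over node indices: k = 2 (cable segments), 3 (triangles)
        or 4 (tetrahedra).
    surface_nodes : (S,) int array
        Indices of nodes forming the mapped surface.
    surface_normals : (S, 3) float array
        Outward unit normals, aligned with ``surface_nodes``.
    surface_faces : (F, 3) int array
        Oriented triangles covering the mapped surface (counter-clockwise
        seen from outside).  Used for phase-singularity rings and topology
        checks.
    """

    nodes: np.ndarray
    elements: np.ndarray
    surface_nodes: np.ndarray
    surface_normals: np.ndarray
    surface_faces: np.ndarray
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.surface_nodes = np.asarray(self.surface_nodes, dtype=np.int64)
        self.surface_normals = np.asarray(self.surface_normals, dtype=float)
        self.surface_faces = np.asarray(self.surface_faces, dtype=np.int64)
        if self.surface_nodes.size == 0:
            raise ValueError("surface_nodes must be non-empty")
        if self.elements.size and self.elements.max() >= len(self.nodes):
            raise ValueError("element index out of range")
        norms = np.linalg.norm(self.surface_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("surface normals must be unit length")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def surface_tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.nodes[self.surface_nodes])
        return self._tree

    def nearest_surface_nodes(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest surface node per query point.

        Ties (equidistant surface nodes) are broken toward the lowest node
        index so placement is deterministic under node permutations of
        everything except the surface ordering.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tree = self.surface_tree()
        k = min(4, len(self.surface_nodes))
        dists, idx = tree.query(points, k=k)
        dists = np.atleast_2d(dists)
        idx = np.atleast_2d(idx)
        best = np.empty(len(points), dtype=np.int64)
        bestd = np.empty(len(points))
        for i in range(len(points)):
            d0 = dists[i, 0]
            tied = dists[i] <= d0 + 1e-12
            cands = self.surface_nodes[idx[i, tied]]
            best[i] = cands.min()
            bestd[i] = d0
        return best, bestd

    def surface_normal_of(self, node: int) -> np.ndarray:
        pos = np.searchsorted(self.surface_nodes, node)
        order = np.argsort(self.surface_nodes)
        sorted_nodes = self.surface_nodes[order]
        pos = np.searchsorted(sorted_nodes, node)
        if pos >= len(sorted_nodes) or sorted_nodes[pos] != node:
            raise KeyError(f"node {node} is not a surface node")
        return self.surface_normals[order[pos]]


@dataclass
class ElectrodeArray:
    """Labelled point electrodes on a logical rows x cols grid.

    ``wrap_cols`` marks arrays whose column axis is periodic (basket splines
    wrap around the azimuth, so spline H is adjacent to spline A); plain
    grids do not wrap.  ``adjacency`` lists, for each electrode with a full
    complement of 8 grid neighbours, the ordered neighbour ring starting at
    the north neighbour and proceeding clockwise viewed from outside the
    tissue; border electrodes carry ``None``.
    """

    labels: list[str]
    positions: np.ndarray
    grid_shape: tuple[int, int]
    nearest_surface_node: np.ndarray
    contact_distance: np.ndarray
    wrap_cols: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.nearest_surface_node = np.asarray(self.nearest_surface_node, dtype=np.int64)
        self.contact_distance = np.asarray(self.contact_distance, dtype=float)
        rows, cols = self.grid_shape
        if len(self.labels) != rows * cols:
            raise ValueError("label count must equal rows*cols")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if np.any(self.contact_distance < 0):
            raise ValueError("contact distances must be non-negative")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def grid_index(self, i: int) -> tuple[int, int]:
        rows, cols = self.grid_shape
        return divmod(i, cols)

    def flat_index(self, row: int, col: int) -> int:
        return row * self.grid_shape[1] + col

    @property
    def adjacency(self) -> list[list[int] | None]:
        rows, cols = self.grid_shape
        out: list[list[int] | None] = []
        for i in range(rows * cols):
            r, c = self.grid_index(i)
            ring: list[int] = []
            ok = True
            for dr, dc in _RING_OFFSETS:
                rr, cc = r + dr, c + dc
                if self.wrap_cols:
                    cc %= cols
                if not (0 <= rr < rows and 0 <= cc < cols):
                    ok = False
                    break
                ring.append(self.flat_index(rr, cc))
            out.append(ring if ok else None)
        return out

    def interior_indices(self) -> list[int]:
        return [i for i, ring in enumerate(self.adjacency) if ring is not None]

    def label_index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class ProjectionStats:
    """Per-electrode surface-projection diagnostics.

    ``mean_neighbor_projection_distance`` is NaN where undefined (border
    electrodes lacking 8 grid neighbours); ``defined`` flags the valid
    entries explicitly.
    """

    labels: list[str]
    distance_to_surface: np.ndarray
    mean_neighbor_projection_distance: np.ndarray
    defined: np.ndarray


def build_sheet_geometry(nx: int, ny: int, spacing: float) -> TissueGeometry:
    """Planar triangulated sheet in the z = 0 plane.

    ``nx`` x ``ny`` nodes at ``spacing`` cm; every node is a surface node
    with outward normal +z.  Each grid cell is split into two triangles with
    counter-clockwise orientation seen from +z.
    """
    if nx < 2 or ny < 2:
        raise ValueError("sheet needs at least 2 nodes per side")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])

    def nid(ix: int, iy: int) -> int:
        return iy * nx + ix

    tris = []
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            a = nid(ix, iy)
            b = nid(ix + 1, iy)
            c = nid(ix + 1, iy + 1)
            d = nid(ix, iy + 1)
            tris.append((a, b, c))
            tris.append((a, c, d))
    elements = np.array(tris, dtype=np.int64)
    surface_nodes = np.arange(nx * ny, dtype=np.int64)
    normals = np.tile([0.0, 0.0, 1.0], (nx * ny, 1))
    return TissueGeometry(nodes, elements, surface_nodes, normals, elements.copy())


def build_shell_geometry(radius: float, subdivisions: int = 3) -> TissueGeometry:
    """Closed triangulated sphere-like shell (icosphere), outward normals."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    nodes = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    normals = nodes / np.linalg.norm(nodes, axis=1, keepdims=True)
    surface_nodes = np.arange(len(nodes), dtype=np.int64)
    return TissueGeometry(nodes, faces, surface_nodes, normals, faces)


def _basket_sphere_points(center: np.ndarray, diameter: float) -> np.ndarray:
    """64 sampling points on the basket sphere: 8 splines at uniform azimuth,
    8 electrodes per spline at uniform polar angle excluding the exact poles.

    Returned row-major over (polar index, spline index): entry ``i*8 + j`` is
    electrode i+1 on spline j (label ``chr(A+j)`` + str(i+1)).
    """
    R = diameter / 2.0
    pts = np.empty((64, 3))
    for i in range(8):  # polar position along spline, 1..8
        theta = np.pi * (i + 0.5) / 8.0
        for j in range(8):  # spline (azimuth)
            phi = 2.0 * np.pi * j / 8.0
            pts[i * 8 + j] = center + R * np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
    return pts


def place_basket_array(
    geom: TissueGeometry,
    center,
    diameter: float = 3.8,
    contact: str = "good",
    standoff: float = 0.05,
) -> ElectrodeArray:
    """Place a 64-electrode basket (8 splines x 8 electrodes, labels A1-H8).

    For each of the 64 sphere sampling points the nearest surface node is
    found; with good contact the electrode sits on the segment from the
    sphere point to that node, ``standoff`` (default 0.05 cm) from the node;
    with poor contact it sits at the segment midpoint.  Basket grids wrap
    azimuthally: spline H is adjacent to spline A, so only the two polar
    rows are border electrodes.
    """
    if contact not in ("good", "poor"):
        raise ValueError("contact must be 'good' or 'poor'")
    center = np.asarray(center, dtype=float)
    sphere_pts = _basket_sphere_points(center, diameter)
    nearest, dists = geom.nearest_surface_nodes(sphere_pts)
    if np.min(dists) > 2.0 * diameter:
        warnings.warn(
            "basket sphere lies far outside the tissue; placement computed anyway",
            stacklevel=2,
        )
    qs = geom.nodes[nearest]
    vec = sphere_pts - qs
    seg_len = np.linalg.norm(vec, axis=1)
    positions = np.empty_like(sphere_pts)
    for k in range(64):
        if contact == "good":
            if seg_len[k] < 1e-12:
                positions[k] = qs[k]
            else:
                t = min(standoff, seg_len[k])
                positions[k] = qs[k] + t * vec[k] / seg_len[k]
        else:
            positions[k] = 0.5 * (sphere_pts[k] + qs[k])
    contact_distance = np.linalg.norm(positions - qs, axis=1)
    labels = [f"{string.ascii_uppercase[j]}{i + 1}" for i in range(8) for j in range(8)]
    return ElectrodeArray(
        labels=labels,
        positions=positions,
        grid_shape=(8, 8),
        nearest_surface_node=nearest,
        contact_distance=contact_distance,
        wrap_cols=True,
    )


def _orthonormal_frame(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane axes (ex, ey) for plane with unit normal n."""
    a = np.zeros(3)
    a[np.argmin(np.abs(n))] = 1.0
    ex = np.cross(a, n)
    ex /= np.linalg.norm(ex)
    ey = np.cross(n, ex)
    return ex, ey


def place_uniform_array(
    geom: TissueGeometry,
    center,
    rows: int = 6,
    cols: int = 6,
    pitch: float = 0.4,
    standoff: float = 0.05,
    normal=None,
) -> ElectrodeArray:
    """Place a uniform grid array (default 6x6, 0.4 cm pitch, labels a1-f6).

    A planar grid is laid out perpendicular to ``normal`` (default: the
    surface normal at the node nearest ``center``); each grid point is then
    snapped to ``standoff`` cm above its nearest surface node along that
    node's outward normal.
    """
    center = np.asarray(center, dtype=float)
    if normal is None:
        node0, _ = geom.nearest_surface_nodes(center[None, :])
        normal = geom.surface_normal_of(int(node0[0]))
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ex, ey = _orthonormal_frame(n)
    # Special case: keep the conventional x/y axes for +z-normal sheets so
    # that label columns run along +x and label rows along -y.
    if np.allclose(n, [0.0, 0.0, 1.0]):
        ex = np.array([1.0, 0.0, 0.0])
        ey = np.array([0.0, 1.0, 0.0])

    pts = np.empty((rows * cols, 3))
    for r in range(rows):
        for c in range(cols):
            u = (c - (cols - 1) / 2.0) * pitch
            v = ((rows - 1) / 2.0 - r) * pitch
            pts[r * cols + c] = center + u * ex + v * ey
    nearest, _ = geom.nearest_surface_nodes(pts)
    order = np.argsort(geom.surface_nodes)
    lookup = dict(zip(geom.surface_nodes[order].tolist(), order.tolist()))
    positions = np.empty_like(pts)
    for k, nd in enumerate(nearest):
        nrm = geom.surface_normals[lookup[int(nd)]]
        positions[k] = geom.nodes[nd] + standoff * nrm
    contact_distance = np.linalg.norm(positions - geom.nodes[nearest], axis=1)
    labels = [
        f"{string.ascii_lowercase[c]}{r + 1}" for r in range(rows) for c in range(cols)
    ]
    return ElectrodeArray(
        labels=labels,
        positions=positions,
        grid_shape=(rows, cols),
        nearest_surface_node=nearest,
        contact_distance=contact_distance,
        wrap_cols=False,
    )


def surface_projection_stats(array: ElectrodeArray, geom: TissueGeometry) -> ProjectionStats:
    """Electrode-to-surface distances and neighbour projection density.

    For each electrode: the distance to its nearest surface node, and (for
    electrodes with a full 8-neighbour ring) the mean Euclidean distance
    from its projected surface node to the projected nodes of its 8 grid
    neighbours.  Border electrodes are flagged undefined.
    """
    proj = geom.nodes[array.nearest_surface_node]
    dist = np.linalg.norm(array.positions - proj, axis=1)
    n = array.n_electrodes
    mean_nb = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for i, ring in enumerate(array.adjacency):
        if ring is None:
            continue
        d = np.linalg.norm(proj[ring] - proj[i], axis=1)
        mean_nb[i] = d.mean()
        defined[i] = True
    return ProjectionStats(
        labels=list(array.labels),
        distance_to_surface=dist,
        mean_neighbor_projection_distance=mean_nb,
        defined=defined,
    )
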