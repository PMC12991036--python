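"""Linear tetrahedral mesh container and structured test geometries.

Coordinates are millimetres throughout. Elements are 4-node tetrahedra with
consistent (positive-volume) orientation. Two-phase meshes additionally carry
a per-element region label distinguishing the dense cortical shell from the
trabecular interior; the label codes are :data:`CORTICAL` and
:data:`TRABECULAR`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TetMesh",
    "CORTICAL",
    "TRABECULAR",
    "REGION_NAMES",
    "make_tube_mesh",
    "make_box_mesh",
]

CORTICAL = 1
TRABECULAR = 0
REGION_NAMES = {CORTICAL: "cortical", TRABECULAR: "trabecular"}

# 6-tet decomposition of a hexahedron around the 0-6 diagonal; conforming
# when every cell uses the same local vertex ordering.
_HEX_TO_TETS = np.array(
    [[0, 1, 2, 6], [0, 2, 3, 6], [0, 3, 7, 6], [0, 7, 4, 6], [0, 4, 5, 6], [0, 5, 1, 6]]
)


@dataclass
class TetMesh:
    """Tetrahedral mesh with named surface node sets.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    tets : (M, 4) int array of node indices, positively oriented
    region_label : optional (M,) int array (CORTICAL / TRABECULAR)
    node_sets : named surface node sets, e.g. ``head``, ``medial_condyle``,
        ``lateral_condyle``, ``outer_surface``
    provenance : generator ground truth (construction axes, radii, ...) kept
        for validation; not used by the analysis itself
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_label: np.ndarray | None = None
    node_sets: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self._volumes = None
        self._centroids = None

    # -- basic quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def signed_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    @property
    def volumes(self) -> np.ndarray:
        """Element volumes, mm^3 (positive for a well-oriented mesh)."""
        if self._volumes is None:
            self._volumes = self.signed_volumes()
        return self._volumes

    @property
    def centroids(self) -> np.ndarray:
        """Element centroids, mm."""
        if self._centroids is None:
            self._centroids = self.nodes[self.tets].mean(axis=1)
        return self._centroids

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    # -- topology ----------------------------------------------------------
    def orient_positive(self) -> None:
        """Swap two nodes of inverted elements so all volumes are positive."""
        v = self.signed_volumes()
        bad = v < 0
        if bad.any():
            self.tets[bad, 1], self.tets[bad, 2] = (
                self.tets[bad, 2].copy(),
                self.tets[bad, 1].copy(),
            )
        self._volumes = None
        self._centroids = None

    def node_adjacency(self):
        """Sparse node-node adjacency through shared elements."""
        pairs = []
        for i in range(4):
            for j in range(i + 1, 4):
                pairs.append(self.tets[:, [i, j]])
        e = np.vstack(pairs)
        a = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(self.n_nodes, self.n_nodes)
        )
        return a + a.T

    def n_connected_components(self) -> int:
        n, _ = connected_components(self.node_adjacency(), directed=False)
        return int(n)

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one tetrahedron."""
        f = self.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
        key = np.sort(f, axis=1)
        _, idx, cnt = np.unique(key, axis=0, return_index=True, return_counts=True)
        return f[idx[cnt == 1]]

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces())

    # -- transforms --------------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TetMesh":
        """Return a rigidly transformed copy: ``p -> R p + t``."""
        rotation = np.asarray(rotation, dtype=float)
        nodes = self.nodes @ rotation.T + np.asarray(translation, dtype=float)
        return TetMesh(
            nodes=nodes,
            tets=self.tets.copy(),
            region_label=None if self.region_label is None else self.region_label.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            provenance=dict(self.provenance),
        )

    def mirrored(self, axis: int = 0) -> "TetMesh":
        """Reflect across one coordinate plane (left/right swap).

        Element orientation is restored after reflection.
        """
        nodes = self.nodes.copy()
        nodes[:, axis] *= -1.0
        m = TetMesh(
            nodes=nodes,
            tets=self.tets.copy(),
            region_label=None if self.region_label is None else self.region_label.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            provenance=dict(self.provenance),
        )
        m.orient_positive()
        return m


def _hexgrid_to_tets(node_id: np.ndarray) -> np.ndarray:
    """Split an (ni, nj, nk) logical grid of node ids into tetrahedra.

    ``node_id[i, j, k]`` gives the global node index; cells are split with the
    uniform 6-tet scheme. Index axes wrap nowhere here; callers handle
    periodicity by constructing ``node_id`` with a repeated first row.
    """
    ni, nj, nk = node_id.shape
    c = node_id[: ni - 1, : nj - 1, : nk - 1]
    corners = np.stack(
        [
            c,
            node_id[1:, : nj - 1, : nk - 1],
            node_id[1:, 1:, : nk - 1],
            node_id[: ni - 1, 1:, : nk - 1],
            node_id[: ni - 1, : nj - 1, 1:],
            node_id[1:, : nj - 1, 1:],
            node_id[1:, 1:, 1:],
            node_id[: ni - 1, 1:, 1:],
        ],
        axis=-1,
    ).reshape(-1, 8)
    return corners[:, _HEX_TO_TETS].reshape(-1, 4)


def make_tube_mesh(
    r_inner: float,
    r_outer: float,
    length: float,
    n_r: int = 3,
    n_theta: int = 16,
    n_z: int = 20,
    interface_radius: float | None = None,
    z0: float = 0.0,
) -> TetMesh:
    """Structured hollow cylinder (annular tube) along +z.

    The tube spans ``z0 <= z <= z0 + length``. ``n_theta`` should be a
    multiple of 4 so that nodes sit exactly on the +/-x and +/-y extremes.
    When ``interface_radius`` is given it is inserted as a nodal ring and
    elements are labelled CORTICAL outside it and TRABECULAR inside,
    producing a crisp two-phase interface.

    Node sets: ``top``, ``bottom``, ``outer_surface``, ``inner_surface``.
    """
    if not (0 <= r_inner < r_outer):
        raise ValueError("need 0 <= r_inner < r_outer")
    radii = np.linspace(r_inner, r_outer, n_r + 1)
    if interface_radius is not None:
        if not (r_inner < interface_radius < r_outer):
            raise ValueError("interface_radius must lie strictly inside the wall")
        radii = np.unique(np.sort(np.append(radii, interface_radius)))
    if r_inner == 0.0:
        radii = radii[radii > 0]
        if radii[0] > 1e-12:
            raise NotImplementedError("solid cylinders are not supported; use r_inner > 0")
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(z0, z0 + length, n_z + 1)
    R, T, Z = np.meshgrid(radii, theta, z, indexing="ij")
    nodes = np.column_stack(
        [(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()]
    )
    node_id = np.arange(nodes.shape[0]).reshape(len(radii), n_theta, len(z))
    # close the ring: append the first angular row so cells wrap around
    node_id = np.concatenate([node_id, node_id[:, :1, :]], axis=1).transpose(1, 0, 2)
    tets = _hexgrid_to_tets(node_id)
    mesh = TetMesh(nodes=nodes, tets=tets)
    mesh.orient_positive()
    v = mesh.signed_volumes()
    keep = v > 1e-12
    mesh = TetMesh(nodes=nodes, tets=mesh.tets[keep])
    if interface_radius is not None:
        r_c = np.hypot(mesh.centroids[:, 0], mesh.centroids[:, 1])
        mesh.region_label = np.where(r_c >= interface_radius, CORTICAL, TRABECULAR)
    r_n = np.hypot(nodes[:, 0], nodes[:, 1])
    tol = 1e-9 * max(r_outer, length)
    mesh.node_sets = {
        "top": np.where(np.abs(nodes[:, 2] - (z0 + length)) < tol)[0],
        "bottom": np.where(np.abs(nodes[:, 2] - z0) < tol)[0],
        "outer_surface": np.where(np.abs(r_n - r_outer) < tol)[0],
        "inner_surface": np.where(np.abs(r_n - radii[0]) < tol)[0],
    }
    mesh.provenance = {
        "kind": "tube",
        "r_inner": float(radii[0]),
        "r_outer": float(r_outer),
        "length": float(length),
        "interface_radius": interface_radius,
        "z0": float(z0),
    }
    return mesh


def make_box_mesh(
    lx: float, ly: float, lz: float, nx: int = 4, ny: int = 4, nz: int = 4
) -> TetMesh:
    """Structured box ``[0, lx] x [0, ly] x [0, lz]`` split into tetrahedra.

    Node sets: the six faces (``x0``, ``x1``, ``y0``, ``y1``, ``z0``, ``z1``).
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    node_id = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    tets = _hexgrid_to_tets(node_id)
    mesh = TetMesh(nodes=nodes, tets=tets)
    mesh.orient_positive()
    tol = 1e-9 * max(lx, ly, lz)
    mesh.node_sets = {
        "x0": np.where(nodes[:, 0] < tol)[0],
        "x1": np.where(nodes[:, 0] > lx - tol)[0],
        "y0": np.where(nodes[:, 1] < tol)[0],
        "y1": np.where(nodes[:, 1] > ly - tol)[0],
        "z0": np.where(nodes[:, 2] < tol)[0],
        "z1": np.where(nodes[:, 2] > lz - tol)[0],
    }
    mesh.provenance = {"kind": "box", "extents": (float(lx), float(ly), float(lz))}
    return mesh
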