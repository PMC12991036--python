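"""Anatomical frame derivation, registration and lesion-station selection.

The hip joint centre (least-squares sphere fit of the femoral head surface)
is the origin of the working frame. The anatomical shaft axis runs through
cross-section centroids at the proximal and distal diaphysis and is aligned
with the superior-inferior (+z) axis; the projection of the condylar line is
aligned with the medial-lateral (+x, medial positive) axis, so the coronal
plane is x-z. The knee joint centre sits at the midpoint of the line joining
the fitted condyle centres, and the mechanical axis joins hip and knee
centres.

Lesion stations are chosen without manual intervention by k-means on node
coordinates: a top-level clustering separates gross regions, the diaphyseal
region is re-clustered into proximal / mid / distal subregions, and the
subregion centroids define the transverse planes of the lesion sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .mesh import TetMesh

__all__ = [
    "AnatomicalFrame",
    "RegionPartition",
    "fit_sphere",
    "compute_frame",
    "kmeans_regions",
]


def fit_sphere(points):
    """Algebraic least-squares sphere fit.

    Solves the linear system in (centre, radius) obtained by expanding
    ``|p - c|^2 = r^2``; exact for noiseless samples of a sphere.

    Returns ``(centre (3,), radius)``. Raises for degenerate (coplanar or
    insufficient) input.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 4:
        raise ValueError("need at least 4 three-dimensional points")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, res, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise ValueError("degenerate sphere fit: points are coplanar or coincident")
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise ValueError("degenerate sphere fit: non-positive radius")
    return centre, float(np.sqrt(r2))


@dataclass
class AnatomicalFrame:
    """Anatomical landmarks and axes, expressed in the registered frame
    (hip centre at the origin, shaft axis +z superior, medial +x).

    ``rotation`` / ``translation`` map original mesh coordinates into this
    frame: ``p_registered = rotation @ p + translation``.
    """

    hip_joint_centre: np.ndarray
    femoral_head_radius: float
    knee_joint_centre: np.ndarray
    shaft_axis: np.ndarray
    neck_axis: np.ndarray
    mechanical_axis: np.ndarray
    condylar_line: np.ndarray
    condyle_medial: np.ndarray
    condyle_lateral: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def condyle_centres(self):
        return self.condyle_medial, self.condyle_lateral

    def with_knee(self, knee: np.ndarray) -> "AnatomicalFrame":
        """Copy with an adjusted knee centre (mechanical axis follows)."""
        knee = np.asarray(knee, dtype=float)
        mech = knee - self.hip_joint_centre
        mech = mech / np.linalg.norm(mech)
        return AnatomicalFrame(
            hip_joint_centre=self.hip_joint_centre.copy(),
            femoral_head_radius=self.femoral_head_radius,
            knee_joint_centre=knee,
            shaft_axis=self.shaft_axis.copy(),
            neck_axis=self.neck_axis.copy(),
            mechanical_axis=mech,
            condylar_line=self.condylar_line.copy(),
            condyle_medial=self.condyle_medial.copy(),
            condyle_lateral=self.condyle_lateral.copy(),
            rotation=self.rotation.copy(),
            translation=self.translation.copy(),
        )

    def to_json(self, path) -> None:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()

        with open(path, "w") as fh:
            json.dump(
                {
                    "hip_joint_centre": arr(self.hip_joint_centre),
                    "femoral_head_radius": self.femoral_head_radius,
                    "knee_joint_centre": arr(self.knee_joint_centre),
                    "shaft_axis": arr(self.shaft_axis),
                    "neck_axis": arr(self.neck_axis),
                    "mechanical_axis": arr(self.mechanical_axis),
                    "condylar_line": arr(self.condylar_line),
                    "condyle_medial": arr(self.condyle_medial),
                    "condyle_lateral": arr(self.condyle_lateral),
                    "rotation": arr(self.rotation),
                    "translation": arr(self.translation),
                },
                fh,
                indent=1,
            )


def _slab_centroid(nodes, t, centre, half=2.5):
    sel = np.abs(t - centre) <= half
    if not sel.any():
        raise ValueError("empty diaphyseal slab; mesh too coarse")
    return nodes[sel].mean(axis=0)


def compute_frame(mesh: TetMesh, register: bool = True):
    """Derive the anatomical frame and rigidly register the mesh into it.

    Requires the named node sets ``head``, ``medial_condyle`` and
    ``lateral_condyle`` (the medial/lateral naming of the inputs is not
    trusted: the medial side is re-identified from the head offset, so a
    mirrored mesh is handled correctly).

    Returns ``(frame, registered_mesh)``; with ``register=False`` the second
    element is the input mesh unchanged.
    """
    for key in ("head", "medial_condyle", "lateral_condyle"):
        if key not in mesh.node_sets or len(mesh.node_sets[key]) < 4:
            raise ValueError(f"mesh lacks the required surface node set {key!r}")
    hip, head_r = fit_sphere(mesh.nodes[mesh.node_sets["head"]])
    ca, _ = fit_sphere(mesh.nodes[mesh.node_sets["medial_condyle"]])
    cb, _ = fit_sphere(mesh.nodes[mesh.node_sets["lateral_condyle"]])

    # rough longitudinal direction from PCA, oriented towards the head
    centred = mesh.nodes - mesh.nodes.mean(axis=0)
    _, _, vt = np.linalg.svd(centred[:: max(1, len(centred) // 5000)], full_matrices=False)
    v0 = vt[0]
    if (hip - mesh.nodes.mean(axis=0)) @ v0 < 0:
        v0 = -v0
    t = mesh.nodes @ v0
    t_hip, t_low = t.max(), t.min()
    span = t_hip - t_low
    # diaphyseal window excludes head/neck (top) and condyles (bottom)
    w_hi = t_hip - 0.30 * span
    w_lo = t_low + 0.18 * span
    c_dist = _slab_centroid(mesh.nodes, t, w_lo + 0.25 * (w_hi - w_lo))
    c_prox = _slab_centroid(mesh.nodes, t, w_lo + 0.75 * (w_hi - w_lo))
    e_z = c_prox - c_dist
    e_z = e_z / np.linalg.norm(e_z)

    knee = 0.5 * (ca + cb)
    # medial = transverse direction from the shaft axis towards the hip centre
    m = hip - c_prox
    m = m - (m @ e_z) * e_z
    m = m / np.linalg.norm(m)
    cond_line = ca - cb
    if cond_line @ m < 0:
        cond_line = -cond_line
        ca, cb = cb, ca
    e_x = cond_line - (cond_line @ e_z) * e_z
    e_x = e_x / np.linalg.norm(e_x)
    e_y = np.cross(e_z, e_x)
    R = np.vstack([e_x, e_y, e_z])
    tvec = -R @ hip

    def reg(p):
        return R @ np.asarray(p, dtype=float) + tvec

    q = c_prox + ((hip - c_prox) @ e_z) * e_z  # shaft-axis point nearest the hip
    neck = hip - q
    neck = neck / np.linalg.norm(neck)

    mech = reg(knee)  # hip is the origin after registration
    mech = mech / np.linalg.norm(mech)
    frame = AnatomicalFrame(
        hip_joint_centre=np.zeros(3),
        femoral_head_radius=head_r,
        knee_joint_centre=reg(knee),
        shaft_axis=np.array([0.0, 0.0, 1.0]),
        neck_axis=R @ neck,
        mechanical_axis=mech,
        condylar_line=np.array([1.0, 0.0, 0.0]),
        condyle_medial=reg(ca),
        condyle_lateral=reg(cb),
        rotation=R,
        translation=tvec,
    )
    registered = mesh.transformed(R, tvec) if register else mesh
    if register and "solid" in registered.provenance:
        # provenance anchors remain in construction coordinates; drop ambiguity
        for key in ("head_centre", "neck_base"):
            registered.provenance[key] = reg(mesh.provenance[key])
    return frame, registered


@dataclass
class RegionPartition:
    """k-means decomposition of the registered femur.

    ``labels`` are top-level cluster ids per node; ``stations`` are the three
    diaphyseal subregion centroids ordered proximal -> distal.
    """

    labels: np.ndarray
    region_centroids: np.ndarray
    diaphysis_labels: np.ndarray  # subregion id per diaphyseal node, -1 elsewhere
    stations: np.ndarray  # (3, 3): proximal, mid, distal
    seed: int

    @property
    def station_names(self):
        return ("proximal", "mid", "distal")


def kmeans_regions(mesh: TetMesh, frame: AnatomicalFrame, seed: int,
                   n_regions: int = 5, n_stations: int = 3) -> RegionPartition:
    """Cluster nodes into anatomical regions and derive diaphyseal stations.

    Top-level k-means (k=``n_regions``) on registered node coordinates;
    clusters containing femoral-head or condyle surface nodes are discarded
    and the remaining (diaphyseal) nodes are re-clustered into
    ``n_stations`` subregions whose centroids, ordered from proximal to
    distal along the shaft axis, are the lesion stations. Deterministic for
    a fixed seed.
    """
    X = mesh.nodes
    km = KMeans(n_clusters=n_regions, random_state=int(seed), n_init=10)
    labels = km.fit_predict(X)
    excluded = set()
    for key in ("head", "medial_condyle", "lateral_condyle"):
        if key in mesh.node_sets and len(mesh.node_sets[key]):
            ids, counts = np.unique(labels[mesh.node_sets[key]], return_counts=True)
            excluded.add(int(ids[np.argmax(counts)]))
    dia_mask = ~np.isin(labels, sorted(excluded))
    if not dia_mask.any():  # degenerate fallback: middle cluster by height
        order = np.argsort(km.cluster_centers_[:, 2])
        dia_mask = labels == order[len(order) // 2]
    km2 = KMeans(n_clusters=n_stations, random_state=int(seed), n_init=10)
    sub = km2.fit_predict(X[dia_mask])
    centroids = km2.cluster_centers_
    order = np.argsort(-centroids[:, 2])  # proximal (high z) first
    stations = centroids[order]
    rank = np.empty(n_stations, dtype=int)
    rank[order] = np.arange(n_stations)
    dia_labels = np.full(mesh.n_nodes, -1, dtype=int)
    dia_labels[dia_mask] = rank[sub]
    return RegionPartition(
        labels=labels,
        region_centroids=km.cluster_centers_,
        diaphysis_labels=dia_labels,
        stations=stations,
        seed=int(seed),
    )
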