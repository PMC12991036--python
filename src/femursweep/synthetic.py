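"""Parametric synthetic femur meshes and synthetic calibrated HU images.

The generator replaces segmented-CT geometry with an idealised solid that
reproduces the gross anatomy controlling stance-load mechanics: a spherical
head, a tapered neck at the neck-shaft angle, a hollow-cortex diaphyseal tube
whose outer radius follows a realistic profile (subtrochanteric flare,
mid-diaphyseal isthmus, distal metaphyseal flare) and a condylar block with
two spherical condyles. Two material modes are supported:

* ``two_phase`` -- composite-femur style, a crisp cortical shell (16.7 GPa)
  around a trabecular core (155 MPa), with explicit region labels;
* ``heterogeneous`` -- a smooth QCT-density field (dense near the surface,
  low in the core) from which calibrated HU voxel images can be synthesised,
  complete with three CaHA phantom rods at 0 / 0.075 / 0.150 g/cm^3.

Tetrahedralisation is a constrained choice: Delaunay over a seeded point
cloud (exact surface samples plus jittered interior grid), keeping tetrahedra
whose centroid is inside the solid. This is fully reproducible and needs no
commercial mesher. The default grid spacing targets a few tens of thousands
of elements -- far below clinical-resolution meshes -- which is adequate for
the trend analyses this package performs (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay
from scipy.sparse.csgraph import connected_components

from .calibration import CalibrationFit
from .mesh import CORTICAL, TRABECULAR, TetMesh

__all__ = [
    "FemurParams",
    "FemurSolid",
    "PhantomROI",
    "VoxelImage",
    "generate_femur",
    "synthesize_hu_image",
    "sample_phantom_hu",
    "measure_head_diameter",
    "measure_diaphyseal_diameter",
    "measure_shaft_length",
    "PHANTOM_DENSITIES",
]

#: Nominal CaHA phantom densities, g/cm^3.
PHANTOM_DENSITIES = (0.0, 0.075, 0.150)

# QCT-equivalent densities (g/cm^3) of the synthetic heterogeneous field.
_RHO_QCT_CORTICAL = 0.85
_RHO_QCT_TRABECULAR = 0.08

# Outer-radius profile of the shaft, normalised to a 35 mm isthmus diameter.
# Knots run from the neck base (s=0) to the condylar junction (s=1).
_PROFILE_S = np.array([0.0, 0.25, 0.55, 0.80, 1.0])
_PROFILE_R = np.array([22.0, 19.5, 17.5, 19.0, 24.0])
_ISTHMUS_S = 0.55

_SHELL_THICKNESS = 2.5  # cortical shell outside the diaphysis, mm


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass(frozen=True)
class FemurParams:
    """Generator parameters (mm / degrees). Defaults sit inside the ranges
    reported for adult femurs (head 50-52 mm, shaft 371-410 mm, diaphyseal
    diameter 35-36 mm, neck-shaft angle 113-127 deg)."""

    shaft_length: float = 400.0
    diaphyseal_outer_diameter: float = 35.0
    #: cortical wall thickness (mm) at equally spaced axial stations along
    #: the shaft, interpolated monotonically in between
    cortical_thickness_profile: tuple = (3.5, 6.0, 6.0, 6.0, 3.5)
    head_diameter: float = 51.0
    neck_shaft_angle: float = 122.0
    anteversion: float = 0.0
    intercondylar_width: float = 90.0
    condyle_centres: tuple | None = None
    material_mode: str = "two_phase"
    seed: int = 1
    #: target point-cloud spacing, mm; controls the element count
    grid_spacing: float = 5.5

    def validate(self) -> None:
        lengths = {
            "shaft_length": self.shaft_length,
            "diaphyseal_outer_diameter": self.diaphyseal_outer_diameter,
            "head_diameter": self.head_diameter,
            "intercondylar_width": self.intercondylar_width,
            "grid_spacing": self.grid_spacing,
        }
        for name, v in lengths.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not (90.0 < self.neck_shaft_angle < 150.0):
            raise ValueError("neck_shaft_angle must lie in (90, 150) degrees")
        t = np.asarray(self.cortical_thickness_profile, dtype=float)
        if t.size < 2 or np.any(t <= 0):
            raise ValueError("cortical_thickness_profile must be >= 2 positive values")
        if np.max(t) >= self.diaphyseal_outer_diameter / 2:
            raise ValueError("cortical thickness exceeds the shaft radius")
        if self.material_mode not in ("two_phase", "heterogeneous"):
            raise ValueError(f"unknown material_mode {self.material_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "FemurParams":
        if "seed" not in d:
            raise ValueError("generator config must state a seed")
        p = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})
        p.validate()
        return p


class FemurSolid:
    """Implicit representation of the parametric femur.

    Provides an approximate signed distance ``phi`` (negative inside),
    region classification, and the smooth QCT-density field used by the
    heterogeneous mode. The construction frame has the hip (head) centre at
    the origin, the shaft axis parallel to z, and the medial direction +x.
    """

    def __init__(self, params: FemurParams):
        params.validate()
        self.params = params
        p = params
        self.R_head = p.head_diameter / 2.0
        theta = np.radians(p.neck_shaft_angle - 90.0)
        av = np.radians(p.anteversion)
        # unit vector from neck base towards the head centre
        self.u_neck = np.array(
            [np.cos(av) * np.sin(theta), np.sin(av) * np.sin(theta), np.cos(theta)]
        )
        self.L_neck = 1.1 * p.head_diameter
        self.B = -self.L_neck * self.u_neck  # neck base on the shaft axis
        self.R_condyle = min(23.0, p.intercondylar_width / 2 - 5.0)
        self.c_off = p.intercondylar_width / 2 - self.R_condyle
        condyle_drop = 1.4 * self.R_condyle
        self.L_tube = p.shaft_length - condyle_drop
        if self.L_tube <= 4 * p.diaphyseal_outer_diameter:
            raise ValueError("shaft_length too small for the condylar block")
        self.z_bot = self.B[2] - self.L_tube
        z_c = self.z_bot - 0.4 * self.R_condyle
        if p.condyle_centres is not None:
            self.condyle_medial = np.asarray(p.condyle_centres[0], dtype=float)
            self.condyle_lateral = np.asarray(p.condyle_centres[1], dtype=float)
        else:
            self.condyle_medial = np.array([self.B[0] + self.c_off, self.B[1], z_c])
            self.condyle_lateral = np.array([self.B[0] - self.c_off, self.B[1], z_c])
        scale = p.diaphyseal_outer_diameter / 35.0
        self._r_outer = PchipInterpolator(_PROFILE_S, _PROFILE_R * scale)
        t = np.asarray(p.cortical_thickness_profile, dtype=float)
        self._t_cort = PchipInterpolator(np.linspace(0, 1, t.size), t)
        self.neck_r_head = 0.72 * self.R_head
        self.neck_r_base = float(self._r_outer(0.0))
        self._box_half = np.array(
            [self.c_off, 0.7 * self.R_condyle, 0.7 * self.R_condyle]
        )
        self._box_centre = np.array([self.B[0], self.B[1], z_c])

    # -- axial parametrisation of the shaft -------------------------------
    def shaft_s(self, z):
        """Normalised axial coordinate along the tube: 0 at the neck base,
        1 at the condylar junction."""
        return (self.B[2] - np.asarray(z, dtype=float)) / self.L_tube

    def outer_radius(self, s):
        return self._r_outer(np.clip(s, 0.0, 1.0))

    def cortical_thickness(self, s):
        return self._t_cort(np.clip(s, 0.0, 1.0))

    @property
    def isthmus_z(self) -> float:
        return self.B[2] - _ISTHMUS_S * self.L_tube

    # -- primitive distances ----------------------------------------------
    def _d_head(self, pts):
        return np.linalg.norm(pts, axis=1) - self.R_head

    def _d_neck(self, pts):
        rel = pts - self.B
        t = np.clip(rel @ self.u_neck / self.L_neck, 0.0, 1.0)
        axis_pt = self.B + np.outer(t * self.L_neck, self.u_neck)
        r = self.neck_r_base + (self.neck_r_head - self.neck_r_base) * t
        return np.linalg.norm(pts - axis_pt, axis=1) - r

    def _d_shaft(self, pts):
        s = self.shaft_s(pts[:, 2])
        radial = (
            np.hypot(pts[:, 0] - self.B[0], pts[:, 1] - self.B[1])
            - self.outer_radius(s)
        )
        axial = np.maximum(pts[:, 2] - self.B[2], self.z_bot - pts[:, 2])
        return np.maximum(radial, axial)

    def _d_condyles(self, pts):
        dm = np.linalg.norm(pts - self.condyle_medial, axis=1) - self.R_condyle
        dl = np.linalg.norm(pts - self.condyle_lateral, axis=1) - self.R_condyle
        return np.minimum(dm, dl)

    def _d_box(self, pts):
        q = np.abs(pts - self._box_centre) - self._box_half
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
        inside = np.minimum(np.max(q, axis=1), 0.0)
        return outside + inside

    def phi(self, pts) -> np.ndarray:
        """Approximate signed distance to the femur surface (neg. inside)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.minimum.reduce(
            [
                self._d_head(pts),
                self._d_neck(pts),
                self._d_shaft(pts),
                self._d_condyles(pts),
                self._d_box(pts),
            ]
        )

    def _pure_shaft_zone(self, pts):
        """Points governed by the tube alone (away from neck and condyles)."""
        pts = np.atleast_2d(pts)
        others = np.minimum.reduce(
            [self._d_head(pts), self._d_neck(pts), self._d_condyles(pts),
             self._d_box(pts)]
        )
        return (self._d_shaft(pts) < others) & (pts[:, 2] < self.B[2] - 1.0) & (
            pts[:, 2] > self.z_bot + 1.0
        )

    def is_cortical(self, pts) -> np.ndarray:
        """Cortical/trabecular classification of interior points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        shaft = self._pure_shaft_zone(pts)
        s = self.shaft_s(pts[:, 2])
        radial = np.hypot(pts[:, 0] - self.B[0], pts[:, 1] - self.B[1])
        in_wall = radial >= self.outer_radius(s) - self.cortical_thickness(s)
        shell = self.phi(pts) > -_SHELL_THICKNESS
        return np.where(shaft, in_wall, shell)

    def local_thickness(self, pts) -> np.ndarray:
        pts = np.atleast_2d(pts)
        t = np.full(pts.shape[0], _SHELL_THICKNESS)
        shaft = self._pure_shaft_zone(pts)
        t[shaft] = self.cortical_thickness(self.shaft_s(pts[shaft, 2]))
        return t

    def density_qct(self, pts) -> np.ndarray:
        """Smooth synthetic QCT density field (g/cm^3), zero outside bone."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        phi = self.phi(pts)
        depth = -phi
        t = self.local_thickness(pts)
        w = 1.0 - _smoothstep((depth - (t - 1.0)) / 2.0)
        rho = _RHO_QCT_TRABECULAR + (_RHO_QCT_CORTICAL - _RHO_QCT_TRABECULAR) * w
        return np.where(phi < 0, rho, 0.0)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def _ring(centre, radius, n, offset, e1=None, e2=None):
    if e1 is None:
        e1, e2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    a = 2 * np.pi * (np.arange(n) + offset) / n
    return centre + np.outer(np.cos(a) * radius, e1) + np.outer(np.sin(a) * radius, e2)


def generate_femur(params: FemurParams) -> TetMesh:
    """Generate a watertight-by-construction tetrahedral femur mesh.

    Deterministic for a fixed ``params.seed``. Surface nodes are placed
    exactly on the analytic surfaces (head sphere, shaft rings, condyle
    spheres), the interior is a jittered grid, and the mesh is the
    centroid-filtered Delaunay tetrahedralisation of the combined cloud.
    Region labels (cortical/trabecular) are attached in both material modes;
    named node sets: ``head``, ``medial_condyle``, ``lateral_condyle``,
    ``outer_surface``.
    """
    params.validate()
    solid = FemurSolid(params)
    h = params.grid_spacing
    rng = np.random.default_rng(params.seed)

    groups: dict[str, list] = {"head": [], "medial_condyle": [], "lateral_condyle": [],
                               "shaft_surface": [], "interface": [], "other_surface": [],
                               "interior": []}

    # shaft outer and interface rings
    n_stations = max(8, int(round(solid.L_tube / (0.9 * h))))
    z_st = np.linspace(solid.B[2], solid.z_bot, n_stations)
    for z in z_st:
        s = float(solid.shaft_s(z))
        c = np.array([solid.B[0], solid.B[1], z])
        for radius, key in (
            (float(solid.outer_radius(s)), "shaft_surface"),
            (float(solid.outer_radius(s) - solid.cortical_thickness(s)), "interface"),
        ):
            n = max(8, int(round(2 * np.pi * radius / h)))
            pts = _ring(c, radius, n, rng.uniform())
            d_others = np.minimum.reduce(
                [solid._d_head(pts), solid._d_neck(pts),
                 solid._d_condyles(pts), solid._d_box(pts)]
            )
            groups[key].append(pts[d_others > -0.3 * h])

    # neck rings
    n_neck = max(4, int(round(solid.L_neck / (0.9 * h))))
    e1 = np.array([solid.u_neck[2], 0.0, -solid.u_neck[0]])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(solid.u_neck, e1)
    for t in np.linspace(0.05, 0.95, n_neck):
        c = solid.B + t * solid.L_neck * solid.u_neck
        radius = solid.neck_r_base + (solid.neck_r_head - solid.neck_r_base) * t
        n = max(8, int(round(2 * np.pi * radius / h)))
        pts = _ring(c, radius, n, rng.uniform(), e1, e2)
        keep = (solid._d_head(pts) > -0.3 * h) & (solid._d_shaft(pts) > -0.3 * h)
        groups["other_surface"].append(pts[keep])

    # head sphere
    n_head = max(60, int(round(4 * np.pi * solid.R_head**2 / h**2)))
    pts = solid.R_head * _fibonacci_sphere(n_head)
    groups["head"].append(pts[solid._d_neck(pts) > 0.2 * h])

    # condyles: keep the inferior portions as sphere caps
    n_cond = max(60, int(round(4 * np.pi * solid.R_condyle**2 / h**2)))
    for centre, other, key in (
        (solid.condyle_medial, solid.condyle_lateral, "medial_condyle"),
        (solid.condyle_lateral, solid.condyle_medial, "lateral_condyle"),
    ):
        pts = centre + solid.R_condyle * _fibonacci_sphere(n_cond)
        keep = (
            (np.linalg.norm(pts - other, axis=1) > solid.R_condyle + 0.2 * h)
            & (solid._d_box(pts) > 0.2 * h)
            & (solid._d_shaft(pts) > 0.2 * h)
        )
        pts = pts[keep]
        cap = pts[:, 2] < centre[2] + 0.35 * solid.R_condyle
        groups[key].append(pts[cap])
        groups["other_surface"].append(pts[~cap])

    # condylar bridge box faces (anterior/posterior and inferior)
    bc, bh = solid._box_centre, solid._box_half
    xs = np.linspace(-bh[0], bh[0], max(2, int(2 * bh[0] / h) + 1))
    zs = np.linspace(-bh[2], bh[2], max(2, int(2 * bh[2] / h) + 1))
    for sign in (-1.0, 1.0):
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        pts = np.column_stack(
            [X.ravel() + bc[0], np.full(X.size, bc[1] + sign * bh[1]), Z.ravel() + bc[2]]
        )
        keep = (solid._d_condyles(pts) > 0.2 * h) & (solid._d_shaft(pts) > 0.2 * h)
        groups["other_surface"].append(pts[keep])

    # interior grid with jitter
    lo = np.array([solid.B[0] - 50, solid.B[1] - 50, solid.z_bot - 1.5 * solid.R_condyle])
    hi = np.array([solid.R_head + 5, 50, solid.R_head + 5])
    axes = [np.arange(lo[i], hi[i] + h, h) for i in range(3)]
    G = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([g.ravel() for g in G])
    # cheap pre-filter before the full distance evaluation
    grid = grid[solid.phi(grid) < -0.45 * h]
    grid = grid + rng.uniform(-0.25 * h, 0.25 * h, size=grid.shape)
    grid = grid[solid.phi(grid) < -0.3 * h]
    groups["interior"].append(grid)

    # assemble the cloud, remembering group index ranges
    order = ["head", "medial_condyle", "lateral_condyle", "shaft_surface",
             "interface", "other_surface", "interior"]
    arrays, ranges, start = [], {}, 0
    for key in order:
        a = np.vstack([x for x in groups[key] if len(x)]) if groups[key] else np.zeros((0, 3))
        arrays.append(a)
        ranges[key] = (start, start + len(a))
        start += len(a)
    points = np.vstack(arrays)

    tri = Delaunay(points)
    tets = tri.simplices
    cent = points[tets].mean(axis=1)
    x = points[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    tets = np.where(vol[:, None] < 0, tets[:, [0, 2, 1, 3]], tets)
    vol = np.abs(vol)
    keep = (solid.phi(cent) < 0.0) & (vol > 1e-4 * h**3)
    tets = tets[keep]

    # largest connected component, then drop unused nodes
    m = TetMesh(nodes=points, tets=tets)
    adj = m.node_adjacency()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        used = labels[tets[:, 0]]
        main = np.bincount(used).argmax()
        tets = tets[used == main]
    used_nodes = np.unique(tets)
    remap = np.full(points.shape[0], -1, dtype=np.int64)
    remap[used_nodes] = np.arange(used_nodes.size)
    mesh = TetMesh(nodes=points[used_nodes], tets=remap[tets])
    mesh.orient_positive()

    def set_from(keys):
        ids = []
        for k in keys:
            a, b = ranges[k]
            ids.append(np.arange(a, b))
        ids = np.concatenate(ids)
        surv = remap[ids]
        return np.sort(surv[surv >= 0])

    mesh.node_sets = {
        "head": set_from(["head"]),
        "medial_condyle": set_from(["medial_condyle"]),
        "lateral_condyle": set_from(["lateral_condyle"]),
        "outer_surface": set_from(
            ["head", "medial_condyle", "lateral_condyle", "shaft_surface",
             "other_surface"]
        ),
    }
    mesh.region_label = np.where(solid.is_cortical(mesh.centroids), CORTICAL, TRABECULAR)
    mesh.provenance = {
        "kind": "femur",
        "params": params,
        "solid": solid,
        "material_mode": params.material_mode,
        "head_centre": np.zeros(3),
        "shaft_axis": np.array([0.0, 0.0, 1.0]),
        "medial_axis": np.array([1.0, 0.0, 0.0]),
        "neck_base": solid.B.copy(),
        "z_bottom_tube": solid.z_bot,
        "condyle_centres": (solid.condyle_medial.copy(), solid.condyle_lateral.copy()),
        "isthmus_z": solid.isthmus_z,
        "diaphysis_z_range": (solid.z_bot, float(solid.B[2])),
    }
    return mesh


# ---------------------------------------------------------------------------
# geometry measurements (validation of the generator against its parameters)
# ---------------------------------------------------------------------------


def measure_head_diameter(mesh: TetMesh) -> float:
    from .anatomy import fit_sphere

    centre, radius = fit_sphere(mesh.nodes[mesh.node_sets["head"]])
    return 2.0 * radius


def measure_diaphyseal_diameter(mesh: TetMesh, slab_halfwidth: float = 3.0) -> float:
    """Outer diameter at the isthmus, from outer-surface nodes."""
    solid = mesh.provenance["solid"]
    z0 = mesh.provenance["isthmus_z"]
    surf = mesh.nodes[mesh.node_sets["outer_surface"]]
    slab = surf[np.abs(surf[:, 2] - z0) <= slab_halfwidth]
    r = np.hypot(slab[:, 0] - solid.B[0], slab[:, 1] - solid.B[1])
    return 2.0 * float(r.max())


def measure_shaft_length(mesh: TetMesh) -> float:
    """Axial extent from the neck base to the distal-most point."""
    return float(mesh.provenance["neck_base"][2] - mesh.nodes[:, 2].min())


# ---------------------------------------------------------------------------
# voxel images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomROI:
    """Cylindrical phantom rod, axis along z."""

    centre_xy: tuple
    radius: float
    z_range: tuple
    nominal_density: float  # g/cm^3


@dataclass
class VoxelImage:
    """Synthetic HU image on a regular grid (axis order x, y, z)."""

    hu: np.ndarray
    spacing: tuple
    origin: tuple
    phantom_rois: list = field(default_factory=list)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def shape(self):
        return self.hu.shape

    def voxel_index(self, points) -> np.ndarray:
        return (np.atleast_2d(points) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def sample(self, points) -> np.ndarray:
        """Trilinear HU interpolation at physical points (mm)."""
        idx = self.voxel_index(points)
        if np.any(idx < -0.5) or np.any(idx > np.array(self.shape) - 0.5):
            raise ValueError("sample point outside the image volume")
        return map_coordinates(self.hu, idx.T, order=1, mode="nearest")

    def roi_mask(self, roi: PhantomROI) -> np.ndarray:
        nx, ny, nz = self.shape
        sp, o = np.asarray(self.spacing), np.asarray(self.origin)
        x = o[0] + sp[0] * np.arange(nx)
        y = o[1] + sp[1] * np.arange(ny)
        z = o[2] + sp[2] * np.arange(nz)
        in_xy = (x[:, None] - roi.centre_xy[0]) ** 2 + (
            y[None, :] - roi.centre_xy[1]
        ) ** 2 <= roi.radius**2
        in_z = (z >= roi.z_range[0]) & (z <= roi.z_range[1])
        return in_xy[:, :, None] & in_z[None, None, :]

    # -- persistence -------------------------------------------------------
    def save(self, basepath: str) -> None:
        """Write `<basepath>.nii.gz` plus a JSON sidecar with ROI metadata."""
        import nibabel as nib

        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.hu.astype(np.float32), affine),
                 basepath + ".nii.gz")
        meta = {
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "phantom_rois": [
                {
                    "centre_xy": list(r.centre_xy),
                    "radius": r.radius,
                    "z_range": list(r.z_range),
                    "nominal_density": r.nominal_density,
                }
                for r in self.phantom_rois
            ],
        }
        with open(basepath + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, basepath: str) -> "VoxelImage":
        import nibabel as nib

        img = nib.load(basepath + ".nii.gz")
        with open(basepath + ".json") as fh:
            meta = json.load(fh)
        rois = [
            PhantomROI(
                centre_xy=tuple(r["centre_xy"]),
                radius=r["radius"],
                z_range=tuple(r["z_range"]),
                nominal_density=r["nominal_density"],
            )
            for r in meta["phantom_rois"]
        ]
        return cls(
            hu=np.asarray(img.dataobj, dtype=np.float32),
            spacing=tuple(meta["spacing"]),
            origin=tuple(meta["origin"]),
            phantom_rois=rois,
        )


def synthesize_hu_image(
    mesh: TetMesh,
    true_calibration: CalibrationFit,
    noise_sd: float = 0.0,
    seed: int = 0,
    spacing: tuple = (0.75, 0.75, 0.25),
    margin: float = 12.0,
) -> VoxelImage:
    """Render the heterogeneous femur's density field into an HU grid.

    Voxels inside bone carry ``HU = (rho_QCT - a) / b`` for the smooth
    synthetic density field, plus Gaussian noise of standard deviation
    ``noise_sd``; background sits at the calibration's zero-density HU.
    Three phantom rods (0 / 0.075 / 0.150 g/cm^3) are placed anterior to the
    bone and recorded as ROIs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    solid = mesh.provenance.get("solid")
    if solid is None or mesh.provenance.get("material_mode") != "heterogeneous":
        raise ValueError(
            "synthesize_hu_image requires a mesh generated in heterogeneous mode"
        )
    rng = np.random.default_rng(seed)
    lo = mesh.nodes.min(axis=0) - margin
    hi = mesh.nodes.max(axis=0) + margin
    # phantom rods anterior (+y) of the bone
    rod_r = 8.0
    rod_y = hi[1] + 6.0 + rod_r
    hi = hi.copy()
    hi[1] = rod_y + rod_r + 6.0
    x_mid = 0.5 * (lo[0] + hi[0])
    z_lo = lo[2] + 0.1 * (hi[2] - lo[2])
    z_hi = hi[2] - 0.1 * (hi[2] - lo[2])
    rois = [
        PhantomROI((x_mid + dx, rod_y), rod_r, (z_lo, z_hi), rho)
        for dx, rho in zip((-3.0 * rod_r, 0.0, 3.0 * rod_r), PHANTOM_DENSITIES)
    ]
    sp = np.asarray(spacing, dtype=float)
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    cal = true_calibration
    hu = np.full(shape, float(cal.hu(0.0)), dtype=np.float32)
    # bone voxels, slab by slab along z to bound memory
    xs = lo[0] + sp[0] * np.arange(shape[0])
    ys = lo[1] + sp[1] * np.arange(shape[1])
    chunk = max(1, int(2e6 / (shape[0] * shape[1])))
    for k0 in range(0, shape[2], chunk):
        k1 = min(k0 + chunk, shape[2])
        zs = lo[2] + sp[2] * np.arange(k0, k1)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        inside = solid.phi(pts) < 0
        if inside.any():
            rho = solid.density_qct(pts[inside])
            block = hu[:, :, k0:k1].reshape(-1)
            block[inside] = cal.hu(rho)
            hu[:, :, k0:k1] = block.reshape(shape[0], shape[1], k1 - k0)
    img = VoxelImage(hu=hu, spacing=tuple(sp), origin=tuple(lo), phantom_rois=rois)
    for roi in rois:
        hu[img.roi_mask(roi)] = float(cal.hu(roi.nominal_density))
    if noise_sd > 0:
        hu += rng.normal(0.0, noise_sd, size=hu.shape).astype(np.float32)
    return img


def sample_phantom_hu(image: VoxelImage):
    """Mean HU of each phantom ROI, ordered by nominal density."""
    if len(image.phantom_rois) == 0:
        raise ValueError("image carries no phantom ROIs")
    out = []
    for roi in sorted(image.phantom_rois, key=lambda r: r.nominal_density):
        mask = image.roi_mask(roi)
        if not mask.any():
            raise ValueError("phantom ROI contains no voxels")
        out.append((roi.nominal_density, float(image.hu[mask].mean())))
    return out
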