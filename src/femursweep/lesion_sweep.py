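"""Spherical lesion insertion and medial-lateral sweep construction.

Osteolytic lesions are modelled as spheres of near-zero stiffness: every
element whose centroid falls inside the sphere has its Young's modulus
replaced by 50 kPa (0.05 MPa). A sweep shifts the lesion centre in 1 mm
steps along the medial-lateral line through a diaphyseal station, in the
transverse plane perpendicular to the shaft axis, spanning the full width of
the bone until the sphere would no longer intersect it.

For two-phase meshes with an explicit cortical-trabecular interface the
sweep also reports the destroyed cortical volume and the transverse cortical
involvement (TCI): the depth by which the lesion sphere penetrates past the
interface into the cortex, measured along the sweep direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import AnatomicalFrame
from .calibration import MaterialField
from .mesh import CORTICAL, TRABECULAR, TetMesh

__all__ = [
    "LesionSpec",
    "SweepPath",
    "build_path",
    "select_lesion_elements",
    "apply_lesion",
    "cortical_volume_loss",
    "compute_tci",
    "detect_tci_case",
    "DEFAULT_LESION_DIAMETER",
    "LESION_MODULUS_MPA",
]

DEFAULT_LESION_DIAMETER = 10.0  # mm
LESION_MODULUS_MPA = 0.05  # 50 kPa


@dataclass
class LesionSpec:
    """One spherical lesion: centre, diameter, replacement modulus and the
    element ids whose centroids fall inside the sphere."""

    centre: np.ndarray
    diameter: float = DEFAULT_LESION_DIAMETER
    lesion_modulus: float = LESION_MODULUS_MPA
    element_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float)
        self.element_ids = np.asarray(self.element_ids, dtype=np.int64)
        if self.diameter <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.lesion_modulus <= 0:
            raise ValueError("lesion modulus must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class SweepPath:
    """Ordered lesion centres along the medial-lateral line of one station.

    ``offsets`` are signed distances (mm) from the station point along the
    medial direction, ordered from the medial extreme to the lateral extreme.
    ``beyond_surface`` flags centres whose sphere extends past the outer
    bone surface (their stiffness-loss is not evaluated);
    ``inside_bone = ~beyond_surface``.
    """

    station: str
    station_point: np.ndarray
    direction: np.ndarray  # unit vector, medial positive
    step: float
    offsets: np.ndarray
    centres: np.ndarray
    beyond_surface: np.ndarray

    @property
    def inside_bone(self) -> np.ndarray:
        return ~self.beyond_surface

    def __len__(self):
        return len(self.offsets)


def build_path(
    frame: AnatomicalFrame,
    station_point,
    mesh: TetMesh,
    step: float = 1.0,
    diameter: float = DEFAULT_LESION_DIAMETER,
    station: str = "",
) -> SweepPath:
    """Construct the medial-lateral sweep through a diaphyseal station.

    The path lies in the transverse plane through ``station_point``
    (perpendicular to the shaft axis) along the medial-lateral axis. It
    includes every centre, on the ``step`` grid, whose lesion sphere still
    intersects the bone; centres whose sphere pokes beyond the outer surface
    are flagged ``beyond_surface``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    p0 = np.asarray(station_point, dtype=float)
    r_l = diameter / 2.0
    direction = frame.condylar_line / np.linalg.norm(frame.condylar_line)
    axis = frame.shaft_axis
    # bone extent along the sweep line, from nodes of elements near the plane
    z = mesh.centroids @ axis
    z0 = p0 @ axis
    slab = np.abs(z - z0) <= r_l + 1.0
    if not slab.any():
        raise ValueError("station point lies outside the mesh")
    nodes = mesh.nodes[np.unique(mesh.tets[slab])]
    x = (nodes - p0) @ direction
    x_min, x_max = float(x.min()), float(x.max())
    if not (x_min < 0 < x_max):
        raise ValueError("station point is not inside the bone cross-section")
    tol = 1e-9
    k_hi = int(np.floor((x_max + r_l - tol) / step))
    k_lo = int(np.ceil((x_min - r_l + tol) / step))
    offsets = np.arange(k_hi, k_lo - 1, -1) * step  # medial -> lateral
    centres = p0 + offsets[:, None] * direction
    beyond = (offsets + r_l > x_max + tol) | (offsets - r_l < x_min - tol)
    return SweepPath(
        station=station,
        station_point=p0,
        direction=direction,
        step=float(step),
        offsets=offsets,
        centres=centres,
        beyond_surface=beyond,
    )


def select_lesion_elements(mesh: TetMesh, centre, diameter: float) -> np.ndarray:
    """Element ids whose centroid lies within the lesion sphere."""
    if diameter <= 0:
        raise ValueError("lesion diameter must be positive")
    centre = np.asarray(centre, dtype=float)
    d2 = np.sum((mesh.centroids - centre) ** 2, axis=1)
    return np.where(d2 <= (diameter / 2.0) ** 2)[0]


def apply_lesion(materials: MaterialField, spec: LesionSpec) -> MaterialField:
    """Return a copy of the field with lesion elements set to the lesion
    modulus; the baseline field is left untouched."""
    if spec.element_ids.size and np.any(
        materials.E[spec.element_ids] < spec.lesion_modulus
    ):
        raise ValueError("lesion modulus exceeds a baseline modulus it replaces")
    out = materials.copy()
    if spec.element_ids.size:
        out.E[spec.element_ids] = spec.lesion_modulus
    return out


def cortical_volume_loss(mesh: TetMesh, spec: LesionSpec) -> float:
    """Total volume (mm^3) of cortical-labelled elements inside the lesion."""
    if mesh.region_label is None:
        raise ValueError(
            "cortical volume loss needs an explicit cortical-trabecular "
            "interface (two-phase mesh); use elasticity loss for "
            "heterogeneous models"
        )
    ids = spec.element_ids
    cort = ids[mesh.region_label[ids] == CORTICAL]
    return float(mesh.volumes[cort].sum())


def compute_tci(mesh: TetMesh, spec: LesionSpec, frame: AnatomicalFrame,
                slab_halfwidth: float | None = None) -> float:
    """Transverse cortical involvement (mm) of one lesion.

    Depth by which the lesion sphere extends past the local cortical-
    trabecular interface, measured along the medial-lateral sweep direction;
    zero when the sphere stays inside the trabecular core, capped at the
    lesion diameter.
    """
    if mesh.region_label is None:
        raise ValueError(
            "TCI requires a two-phase mesh; use detect_tci_case on the sweep "
            "records for heterogeneous models"
        )
    r_l = spec.radius
    direction = frame.condylar_line / np.linalg.norm(frame.condylar_line)
    axis = frame.shaft_axis
    half = r_l + 1.0 if slab_halfwidth is None else slab_halfwidth
    z = mesh.centroids @ axis
    z0 = spec.centre @ axis
    slab = np.abs(z - z0) <= half
    trab = slab & (mesh.region_label == TRABECULAR)
    if not trab.any():
        raise ValueError("no trabecular elements near the lesion plane")
    trab_nodes = mesh.nodes[np.unique(mesh.tets[trab])]
    x_t = trab_nodes @ direction
    # local transverse position of the section centre and the two interfaces
    x_int_med, x_int_lat = float(x_t.max()), float(x_t.min())
    xc = float(spec.centre @ direction)
    pen_med = xc + r_l - x_int_med
    pen_lat = x_int_lat - (xc - r_l)
    return float(np.clip(max(pen_med, pen_lat), 0.0, 2.0 * r_l))


def detect_tci_case(elasticity_losses, target_mm: int = 3) -> int:
    """Index of the case with ``target_mm`` mm of TCI, from the loss series.

    The records must be ordered along the path from the trabecular core
    outward. Walking the series, the first strict increase in elasticity-loss
    magnitude marks the lesion entering the cortex; the ``target_mm``-th
    consecutive increasing record is returned (each 1 mm step past the
    interface adds one increasing record, so ``target_mm=3`` picks the case
    with approximately 3 mm of cortical involvement).
    """
    v = np.abs(np.asarray(elasticity_losses, dtype=float))
    if target_mm < 1:
        raise ValueError("target_mm must be >= 1")
    inc = np.where(np.diff(v) > 0)[0] + 1
    if inc.size == 0:
        raise ValueError("elasticity-loss series shows no increase")
    i0 = inc[0]
    idx = i0 + target_mm - 1
    if idx >= v.size or np.any(np.diff(v[i0 - 1: idx + 1]) <= 0):
        raise ValueError(
            f"fewer than {target_mm} consecutive increasing records after the "
            "first cortical involvement"
        )
    return int(idx)
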