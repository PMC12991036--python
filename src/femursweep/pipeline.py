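"""End-to-end lesion-location sensitivity analysis.

The pipeline generates (or accepts) a femur mesh, assigns materials, derives
the anatomical frame, balances the knee-centre position so the stance load
produces the physiological 55:45 medial:lateral condyle reaction split with
the hip deflecting in the coronal plane, then sweeps a spherical lesion
across the medial-lateral line of the proximal-, mid- and distal-diaphyseal
stations, recording for every lesion position:

* elasticity-loss (MPa): the volume-weighted modulus deficit over the lesion
  elements, ``(sum V_i E_i^1 - sum V_i E_i^0) / sum V_i`` -- a proxy for
  cortical destruction (negative for osteolytic lesions);
* stiffness-loss (N/mm == kN/m): ``R1/U1 - R0/U0`` where R is the applied
  force magnitude and U the hip-centre displacement magnitude, lesioned (1)
  versus lesion-free (0);
* transverse cortical involvement and cortical volume loss (two-phase mesh);
* peak probed principal strains along the station's medial-lateral line.

Losses are normalised per femur by the largest loss magnitude, matching how
multi-subject trends are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .anatomy import AnatomicalFrame, compute_frame, kmeans_regions
from .calibration import MaterialField, assign_materials
from .fe_core import (
    ConstrainedSystem,
    FEModel,
    LoadCase,
    SolveResult,
    Tie,
    probe_strain,
    stance_load_magnitude,
)
from .lesion_sweep import (
    DEFAULT_LESION_DIAMETER,
    LESION_MODULUS_MPA,
    LesionSpec,
    SweepPath,
    apply_lesion,
    build_path,
    compute_tci,
    cortical_volume_loss,
    select_lesion_elements,
)
from .mesh import TetMesh
from .synthetic import FemurParams, generate_femur

__all__ = [
    "RunConfig",
    "BalanceResult",
    "SweepResult",
    "elasticity_loss",
    "stiffness_loss",
    "balance_knee_centre",
    "run_sweep",
    "normalise_and_summarise",
    "strain_profile",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full sweep run."""

    femur: FemurParams = field(default_factory=FemurParams)
    body_mass_kg: float = 68.0
    load_multiple: float = 7.5
    condyle_ratio_target: float = 0.55
    #: tolerance on the medial fraction, as a fraction of the total
    #: (0.001 == +/-0.1 percentage point)
    condyle_ratio_tol: float = 0.001
    coronal_tol: float = 1e-3  # |u_y| / |u| at the hip reference
    stations: tuple = ("proximal", "mid", "distal")
    lesion_diameter: float = DEFAULT_LESION_DIAMETER
    lesion_modulus: float = LESION_MODULUS_MPA
    step: float = 1.0
    #: strain probes use a sphere scaled to the coarse desk-scale meshes
    probe_radius: float = 4.0
    profile_spacing: float = 2.0
    compute_strain_profiles: bool = True
    seed: int = 1

    def validate(self) -> None:
        if not (0.5 < self.condyle_ratio_target < 1.0):
            raise ValueError("condyle_ratio_target must lie in (0.5, 1)")
        if self.condyle_ratio_tol <= 0:
            raise ValueError("condyle_ratio_tol must be positive")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.lesion_diameter <= 0 or self.lesion_modulus <= 0:
            raise ValueError("lesion diameter and modulus must be positive")
        self.femur.validate()

    @property
    def load_magnitude(self) -> float:
        return stance_load_magnitude(self.body_mass_kg, self.load_multiple)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        femur = d.pop("femur", None)
        cfg = cls(**d)
        if femur is not None:
            cfg.femur = FemurParams.from_dict(femur)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def elasticity_loss(mesh: TetMesh, baseline: MaterialField,
                    lesioned: MaterialField, element_ids) -> float:
    """Volume-weighted modulus change over the lesion elements (MPa).

    ``(sum_i V_i E_i^1 - sum_i V_i E_i^0) / sum_i V_i`` over the lesion's
    element set; negative for a destructive lesion.
    """
    ids = np.asarray(element_ids, dtype=np.int64)
    if ids.size == 0:
        raise ValueError("elasticity loss needs a non-empty element set")
    V = mesh.volumes[ids]
    return float((V @ lesioned.E[ids] - V @ baseline.E[ids]) / V.sum())


def stiffness_loss(with_lesion: SolveResult, baseline: SolveResult,
                   ref: str = "hip") -> float:
    """``R1/U1 - R0/U0`` in N/mm; R = applied force magnitude, U = hip
    reference displacement magnitude."""
    R1 = float(np.linalg.norm(with_lesion.applied_force))
    R0 = float(np.linalg.norm(baseline.applied_force))
    U1 = with_lesion.hip_displacement_magnitude(ref)
    U0 = baseline.hip_displacement_magnitude(ref)
    if U0 == 0 or U1 == 0:
        raise ValueError("zero hip displacement; load case is degenerate")
    return R1 / U1 - R0 / U0


@dataclass
class BalanceResult:
    frame: AnatomicalFrame
    load_case: LoadCase
    baseline: SolveResult
    medial_fraction: float
    coronal_residual: float
    n_solves: int
    model: FEModel
    system: ConstrainedSystem
    factorisation: object


def _stance_load_case(mesh: TetMesh, frame: AnatomicalFrame,
                      load_vector=np.zeros(3)) -> LoadCase:
    return LoadCase(
        ties=[
            Tie("hip", mesh.node_sets["head"], frame.hip_joint_centre, fixed=False),
            Tie("medial_condyle", mesh.node_sets["medial_condyle"],
                frame.condyle_medial, fixed=True),
            Tie("lateral_condyle", mesh.node_sets["lateral_condyle"],
                frame.condyle_lateral, fixed=True),
        ],
        load_tie="hip",
        load_vector=load_vector,
    )


def balance_knee_centre(
    mesh: TetMesh,
    materials: MaterialField,
    frame: AnatomicalFrame,
    config: RunConfig | None = None,
    target: float | None = None,
    max_rounds: int = 12,
) -> BalanceResult:
    """Adjust the knee joint centre until the stance load is balanced.

    The load (``7.5 x body weight`` by default) acts at the hip reference
    along the mechanical axis (hip centre -> knee centre). The knee centre is
    moved in the condylar plane -- medial-lateral and antero-posterior -- by
    damped 1-D root bracketing until (a) the medial condyle carries
    ``target`` of the total reaction magnitude within the configured
    tolerance and (b) the hip displacement lies in the coronal plane. The
    stiffness factorisation is reused, so each iteration is a cheap
    triangular solve.
    """
    config = config or RunConfig()
    target = config.condyle_ratio_target if target is None else target
    magnitude = config.load_magnitude
    lc = _stance_load_case(mesh, frame)
    model = FEModel(mesh, materials)
    system = ConstrainedSystem(mesh, lc)
    fact = system.factorize(model.stiffness())

    hip = frame.hip_joint_centre
    kz = float(frame.knee_joint_centre[2])
    n_solves = 0
    cache: dict = {}

    def solve_at(kx: float, ky: float) -> SolveResult:
        nonlocal n_solves
        key = (round(kx, 9), round(ky, 9))
        if key not in cache:
            knee = np.array([kx, ky, kz])
            d = knee - hip
            d = d / np.linalg.norm(d)
            cache[key] = fact.solve(model, load_vector=magnitude * d)
            n_solves += 1
        return cache[key]

    def medial_resid(kx, ky):
        r = solve_at(kx, ky)
        rm = np.linalg.norm(r.reactions["medial_condyle"])
        rl = np.linalg.norm(r.reactions["lateral_condyle"])
        return rm / (rm + rl) - target

    def coronal_resid(kx, ky):
        r = solve_at(kx, ky)
        u = r.ref_displacements["hip"]
        return float(u[1] / max(np.linalg.norm(u), 1e-30))

    span = float(np.linalg.norm(frame.condyle_medial - frame.condyle_lateral))
    kx_lo = float(frame.condyle_lateral[0]) - 0.25 * span
    kx_hi = float(frame.condyle_medial[0]) + 0.25 * span
    ky_lo, ky_hi = float(frame.knee_joint_centre[1]) - 0.5 * span, float(
        frame.knee_joint_centre[1]
    ) + 0.5 * span
    kx = float(frame.knee_joint_centre[0])
    ky = float(frame.knee_joint_centre[1])
    for _ in range(max_rounds):
        f_lo, f_hi = medial_resid(kx_lo, ky), medial_resid(kx_hi, ky)
        if f_lo * f_hi > 0:
            raise RuntimeError(
                "no knee-centre position in the condylar span reaches the "
                f"target medial fraction; residuals {f_lo:.4f}, {f_hi:.4f}"
            )
        kx = brentq(lambda x: medial_resid(x, ky), kx_lo, kx_hi,
                    xtol=1e-6, rtol=1e-12)
        if abs(coronal_resid(kx, ky)) > config.coronal_tol:
            g_lo, g_hi = coronal_resid(kx, ky_lo), coronal_resid(kx, ky_hi)
            if g_lo * g_hi <= 0:
                ky = brentq(lambda y: coronal_resid(kx, y), ky_lo, ky_hi,
                            xtol=1e-6, rtol=1e-12)
        r1 = medial_resid(kx, ky)
        r2 = coronal_resid(kx, ky)
        if abs(r1) <= config.condyle_ratio_tol and abs(r2) <= config.coronal_tol:
            break
    else:
        raise RuntimeError(
            f"knee balancing did not converge: medial residual {r1:.5f}, "
            f"coronal residual {r2:.2e}"
        )
    result = solve_at(kx, ky)
    knee = np.array([kx, ky, kz])
    new_frame = frame.with_knee(knee)
    direction = (knee - hip) / np.linalg.norm(knee - hip)
    lc_final = _stance_load_case(mesh, new_frame, magnitude * direction)
    rm = np.linalg.norm(result.reactions["medial_condyle"])
    rl = np.linalg.norm(result.reactions["lateral_condyle"])
    return BalanceResult(
        frame=new_frame,
        load_case=lc_final,
        baseline=result,
        medial_fraction=float(rm / (rm + rl)),
        coronal_residual=abs(coronal_resid(kx, ky)),
        n_solves=n_solves,
        model=model,
        system=system,
        factorisation=fact,
    )


@dataclass
class SweepResult:
    records: pd.DataFrame
    summary: dict
    mesh: TetMesh
    frame: AnatomicalFrame
    materials: MaterialField
    baseline: SolveResult
    load_case: LoadCase
    paths: dict
    balance: BalanceResult


def _profile_points(path: SweepPath, spacing: float):
    # probe only where the lesion sphere fits inside the bone, so every
    # probe point is surrounded by elements
    inside = path.offsets[path.inside_bone]
    if inside.size == 0:
        raise ValueError(f"no inside-bone lesion positions at {path.station!r}")
    offs = np.arange(inside.min(), inside.max() + 1e-9, spacing)
    return path.station_point + offs[:, None] * path.direction, offs


def run_sweep(config: RunConfig, mesh: TetMesh | None = None,
              materials: MaterialField | None = None) -> SweepResult:
    """Run the full lesion-location sensitivity analysis.

    Generates the femur (unless a mesh is supplied), balances the stance
    load, solves the lesion-free baseline once, then one constrained solve
    per lesion position per station. Solver failures on individual cases are
    logged and recorded as missing; the sweep continues. Deterministic for a
    fixed config.
    """
    config.validate()
    if mesh is None:
        mesh = generate_femur(config.femur)
    if materials is None:
        materials = assign_materials(mesh, None, None, config.femur.material_mode)
    frame, mesh = compute_frame(mesh)
    regions = kmeans_regions(mesh, frame, seed=config.seed)
    bal = balance_knee_centre(mesh, materials, frame, config)
    frame = bal.frame
    model, system = bal.model, bal.system
    baseline = bal.baseline
    K_base = model.stiffness()

    two_phase = mesh.region_label is not None
    station_points = dict(zip(regions.station_names, regions.stations))
    rows = []
    paths = {}
    for station in config.stations:
        path = build_path(frame, station_points[station], mesh,
                          step=config.step, diameter=config.lesion_diameter,
                          station=station)
        paths[station] = path
        if config.compute_strain_profiles:
            probe_pts, _ = _profile_points(path, config.profile_spacing)
        for i, off in enumerate(path.offsets):
            rec = {
                "station": station,
                "offset_mm": float(off),
                "side": "medial" if off >= 0 else "lateral",
                "x": path.centres[i, 0],
                "y": path.centres[i, 1],
                "z": path.centres[i, 2],
                "inside_bone": bool(path.inside_bone[i]),
                "elasticity_loss_mpa": np.nan,
                "stiffness_loss_n_per_mm": np.nan,
                "tci_mm": np.nan,
                "cortical_volume_loss_mm3": np.nan,
                "peak_emax": np.nan,
                "peak_abs_emin": np.nan,
                "n_lesion_elements": 0,
            }
            ids = select_lesion_elements(mesh, path.centres[i], config.lesion_diameter)
            rec["n_lesion_elements"] = int(ids.size)
            if ids.size == 0:
                rows.append(rec)
                continue
            spec = LesionSpec(centre=path.centres[i],
                              diameter=config.lesion_diameter,
                              lesion_modulus=config.lesion_modulus,
                              element_ids=ids)
            lesioned = apply_lesion(materials, spec)
            rec["elasticity_loss_mpa"] = elasticity_loss(mesh, materials, lesioned, ids)
            if two_phase:
                rec["cortical_volume_loss_mm3"] = cortical_volume_loss(mesh, spec)
                rec["tci_mm"] = compute_tci(mesh, spec, frame)
            if path.inside_bone[i]:
                try:
                    dK = model.stiffness_subset(ids, lesioned.E[ids] - materials.E[ids])
                    res = system.factorize(K_base + dK.tocsr()).solve(
                        model, load_vector=bal.load_case.load_vector)
                    rec["stiffness_loss_n_per_mm"] = stiffness_loss(res, baseline)
                    if config.compute_strain_profiles:
                        emax = []
                        emin = []
                        for p in probe_pts:
                            a, b = probe_strain(res, mesh, p, config.probe_radius)
                            emax.append(a)
                            emin.append(b)
                        rec["peak_emax"] = float(np.max(emax))
                        rec["peak_abs_emin"] = float(np.max(np.abs(emin)))
                except Exception as err:  # missing-case policy: log, continue
                    log.warning("lesion case %s offset %+.0f mm failed: %s",
                                station, off, err)
            rows.append(rec)
    records = pd.DataFrame(rows)
    records, summary = normalise_and_summarise(records)
    return SweepResult(
        records=records,
        summary=summary,
        mesh=mesh,
        frame=frame,
        materials=materials,
        baseline=baseline,
        load_case=bal.load_case,
        paths=paths,
        balance=bal,
    )


def normalise_and_summarise(records: pd.DataFrame):
    """Normalise losses per femur and summarise the extremes.

    Each loss column is divided by its largest magnitude, giving normalised
    values in [-1, 0] with the per-femur extreme at -1. The summary reports
    the maximum-magnitude elasticity- and stiffness-loss with their station
    and medial/lateral side.
    """
    if len(records) == 0:
        raise ValueError("no sweep records to summarise")
    records = records.copy()
    summary = {}
    for col, name in (
        ("elasticity_loss_mpa", "elasticity_loss"),
        ("stiffness_loss_n_per_mm", "stiffness_loss"),
    ):
        vals = records[col].to_numpy()
        finite = np.isfinite(vals)
        scale = np.nanmax(np.abs(vals)) if finite.any() else np.nan
        if not finite.any() or scale == 0:
            records[f"normalised_{name}"] = np.nan
            summary[name] = {"max": 0.0, "note": "no cortical involvement"}
            continue
        records[f"normalised_{name}"] = vals / scale
        i = int(np.nanargmax(np.abs(vals)))
        summary[name] = {
            "max": float(vals[i]),
            "station": str(records["station"].iloc[i]),
            "side": str(records["side"].iloc[i]),
            "offset_mm": float(records["offset_mm"].iloc[i]),
        }
    if "cortical_volume_loss_mm3" in records:
        cvl = records["cortical_volume_loss_mm3"].to_numpy()
        if np.isfinite(cvl).any() and np.nanmax(cvl) > 0:
            records["normalised_cortical_volume_loss"] = cvl / np.nanmax(cvl)
    return records, summary


def strain_profile(result: SolveResult, mesh: TetMesh, line_points,
                   radius: float = 4.0) -> pd.DataFrame:
    """Probed principal strains along an ordered line of points.

    Returns a table of (position along the line, mean eps_max, mean eps_min);
    used to compare lesion-free, 0 mm TCI and 3 mm TCI cases along the
    medial-lateral line through a station.
    """
    pts = np.atleast_2d(np.asarray(line_points, dtype=float))
    pos = np.linalg.norm(pts - pts[0], axis=1)
    rows = []
    for p, s in zip(pts, pos):
        emax, emin = probe_strain(result, mesh, p, radius)
        rows.append({"position_mm": float(s), "mean_emax": emax, "mean_emin": emin})
    return pd.DataFrame(rows)
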