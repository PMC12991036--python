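"""Principal-strain profiles along the medial-lateral line of the mid
station, comparing lesion-free, ~0 mm TCI and ~3 mm TCI medial lesions.

Strains are spherical-probe means to suppress single-element concentrations.
"""

import dataclasses

import numpy as np

from femursweep import (
    ConstrainedSystem,
    FEModel,
    FemurParams,
    LesionSpec,
    RunConfig,
    apply_lesion,
    assign_materials,
    balance_knee_centre,
    build_path,
    compute_frame,
    compute_tci,
    generate_femur,
    kmeans_regions,
    select_lesion_elements,
    strain_profile,
)

params = dataclasses.replace(FemurParams(seed=1), grid_spacing=8.0)
config = RunConfig(femur=params, probe_radius=6.0)
mesh = generate_femur(params)
materials = assign_materials(mesh, None, None, params.material_mode)
frame, mesh = compute_frame(mesh)
regions = kmeans_regions(mesh, frame, seed=params.seed)
bal = balance_knee_centre(mesh, materials, frame, config)

station = dict(zip(regions.station_names, regions.stations))["mid"]
path = build_path(bal.frame, station, mesh)
model, system = bal.model, bal.system
K = model.stiffness()

# pick the medial lesion positions closest to 0 mm and 3 mm of TCI
cases = {"lesion-free": None}
for target in (0.0, 3.0):
    best = min(
        (off for off, ok in zip(path.offsets, path.inside_bone) if ok and off > 0),
        key=lambda off: abs(
            compute_tci(mesh, LesionSpec(path.station_point
                                         + off * path.direction), bal.frame)
            - target
        ),
    )
    cases[f"~{target:.0f} mm TCI (offset {best:+.0f} mm)"] = best

inside = path.offsets[path.inside_bone]
line = [path.station_point + o * path.direction
        for o in np.arange(inside.min(), inside.max() + 1e-9, 2.0)]

for label, off in cases.items():
    if off is None:
        res = bal.baseline
    else:
        centre = path.station_point + off * path.direction
        ids = select_lesion_elements(mesh, centre, config.lesion_diameter)
        lesioned = apply_lesion(materials, LesionSpec(centre, element_ids=ids))
        dK = model.stiffness_subset(ids, lesioned.E[ids] - materials.E[ids])
        res = system.factorize(K + dK.tocsr()).solve(
            model, load_vector=bal.load_case.load_vector)
    prof = strain_profile(res, mesh, line, radius=config.probe_radius)
    print(f"\n{label}:")
    print(f"  peak tensile strain     {prof.mean_emax.max():+.2e}")
    print(f"  peak compressive strain {prof.mean_emin.min():+.2e}")
    print(f"  (compression dominates: "
          f"{abs(prof.mean_emin.min()) > prof.mean_emax.max()})")
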