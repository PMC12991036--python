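"""Generate a synthetic femur, derive its anatomical frame and stations,
and export everything to VTK for inspection in ParaView.
"""

import numpy as np

from femursweep import (
    FemurParams,
    compute_frame,
    generate_femur,
    kmeans_regions,
    measure_diaphyseal_diameter,
    measure_head_diameter,
    measure_shaft_length,
    write_vtk,
)

params = FemurParams(seed=1)  # the default two-phase femur
mesh = generate_femur(params)
print(f"{mesh.n_elements} elements, {mesh.n_nodes} nodes, "
      f"{mesh.total_volume / 1e3:.0f} cm^3")
print(f"head diameter      {measure_head_diameter(mesh):6.1f} mm "
      f"(target {params.head_diameter})")
print(f"diaphyseal diameter{measure_diaphyseal_diameter(mesh):6.1f} mm "
      f"(target {params.diaphyseal_outer_diameter})")
print(f"shaft length       {measure_shaft_length(mesh):6.1f} mm "
      f"(target {params.shaft_length})")

frame, mesh = compute_frame(mesh)  # registered: hip at origin, medial +x
print(f"hip joint centre {frame.hip_joint_centre}, head radius "
      f"{frame.femoral_head_radius:.1f} mm")
print(f"knee joint centre {np.round(frame.knee_joint_centre, 1)}")
print(f"mechanical axis {np.round(frame.mechanical_axis, 3)}")

regions = kmeans_regions(mesh, frame, seed=params.seed)
for name, centre in zip(regions.station_names, regions.stations):
    print(f"station {name:9s} at {np.round(centre, 1)}")

write_vtk("femur.vtk", mesh,
          cell_data={"region_label": mesh.region_label},
          point_data={"kmeans_region": regions.labels.astype(float),
                      "diaphysis_station": regions.diaphysis_labels.astype(float)})
print("wrote femur.vtk")
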