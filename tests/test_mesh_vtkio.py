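"""Mesh containers, structured test geometries and VTK round trips."""

import numpy as np
import pytest

from femursweep import (
    CORTICAL,
    TRABECULAR,
    TetMesh,
    make_box_mesh,
    make_tube_mesh,
    read_vtk,
    write_vtk,
)


def test_box_mesh_volume_exact():
    mesh = make_box_mesh(10.0, 20.0, 30.0, nx=3, ny=4, nz=5)
    assert mesh.total_volume == pytest.approx(10.0 * 20.0 * 30.0, rel=1e-12)
    assert np.all(mesh.signed_volumes() > 0)
    assert mesh.n_connected_components() == 1


def test_tube_mesh_volume_matches_polygonal_annulus(two_phase_tube):
    # straight-sided cells: exact volume is the inscribed-polygon annulus
    n = 24
    poly = 0.5 * n * np.sin(2 * np.pi / n)
    expected = poly * (20.0**2 - 10.0**2) * 100.0
    assert two_phase_tube.total_volume == pytest.approx(expected, rel=1e-10)
    # and within a few percent of the true annulus
    true = np.pi * (20.0**2 - 10.0**2) * 100.0
    assert abs(two_phase_tube.total_volume - true) / true < 0.03


def test_tube_interface_is_crisp(two_phase_tube):
    r = np.hypot(two_phase_tube.centroids[:, 0], two_phase_tube.centroids[:, 1])
    cort = two_phase_tube.region_label == CORTICAL
    assert np.all(r[cort] >= 12.5)
    assert np.all(r[~cort] <= 12.5)
    assert set(np.unique(two_phase_tube.region_label)) == {CORTICAL, TRABECULAR}


def test_tube_node_sets(two_phase_tube):
    ns = two_phase_tube.node_sets
    nodes = two_phase_tube.nodes
    assert np.allclose(nodes[ns["top"], 2], 100.0)
    assert np.allclose(nodes[ns["bottom"], 2], 0.0)
    assert np.allclose(np.hypot(*nodes[ns["outer_surface"], :2].T), 20.0)
    assert np.allclose(np.hypot(*nodes[ns["inner_surface"], :2].T), 10.0)


def test_boundary_nodes_of_box_are_surface_nodes():
    mesh = make_box_mesh(1.0, 1.0, 1.0, nx=3, ny=3, nz=3)
    surf = mesh.boundary_nodes()
    on_face = np.zeros(mesh.n_nodes, dtype=bool)
    for axis in range(3):
        on_face |= np.isclose(mesh.nodes[:, axis], 0.0)
        on_face |= np.isclose(mesh.nodes[:, axis], 1.0)
    assert set(surf.tolist()) == set(np.where(on_face)[0].tolist())


def test_transformed_and_mirrored_preserve_volume(two_phase_tube):
    theta = 0.3
    R = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    moved = two_phase_tube.transformed(R, np.array([1.0, -2.0, 3.0]))
    assert moved.total_volume == pytest.approx(two_phase_tube.total_volume)
    assert np.all(moved.signed_volumes() > 0)
    mirrored = two_phase_tube.mirrored(axis=0)
    assert mirrored.total_volume == pytest.approx(two_phase_tube.total_volume)
    assert np.all(mirrored.signed_volumes() > 0)


def test_orient_positive_fixes_inverted_elements():
    mesh = make_box_mesh(1.0, 1.0, 1.0, nx=2, ny=2, nz=2)
    tets = mesh.tets.copy()
    tets[::2, [0, 1]] = tets[::2, [1, 0]]  # invert half the elements
    bad = TetMesh(nodes=mesh.nodes, tets=tets)
    bad.orient_positive()
    assert np.all(bad.signed_volumes() > 0)


def test_vtk_round_trip(tmp_path, two_phase_tube):
    path = tmp_path / "tube.vtk"
    cell_data = {"region": two_phase_tube.region_label.astype(float)}
    point_data = {"z": two_phase_tube.nodes[:, 2]}
    write_vtk(path, two_phase_tube, cell_data=cell_data, point_data=point_data)
    mesh, cd, pd_ = read_vtk(path)
    assert np.allclose(mesh.nodes, two_phase_tube.nodes)
    assert np.array_equal(mesh.tets, two_phase_tube.tets)
    assert np.allclose(cd["region"], cell_data["region"])
    assert np.allclose(pd_["z"], point_data["z"])
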