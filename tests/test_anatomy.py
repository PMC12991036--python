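"""Sphere fitting, anatomical frame derivation, k-means stations."""

import numpy as np
import pytest

from femursweep import compute_frame, fit_sphere, kmeans_regions


def test_fit_sphere_exact(rng):
    centre = np.array([3.0, -2.0, 7.0])
    radius = 25.5
    dirs = rng.normal(size=(200, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = centre + radius * dirs
    c, r = fit_sphere(pts)
    assert c == pytest.approx(centre, abs=1e-9)
    assert r == pytest.approx(radius, abs=1e-9)


def test_fit_sphere_partial_cap(rng):
    # only a polar cap is visible on a femoral head; the fit must still work
    centre = np.zeros(3)
    phi = rng.uniform(0, 2 * np.pi, 300)
    theta = rng.uniform(0, 0.45 * np.pi, 300)  # upper cap only
    pts = centre + 25.0 * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    c, r = fit_sphere(pts)
    assert c == pytest.approx(centre, abs=1e-8)
    assert r == pytest.approx(25.0, abs=1e-8)


def test_fit_sphere_rejects_degenerate_input(rng):
    planar = np.column_stack([rng.normal(size=(20, 2)), np.zeros(20)])
    with pytest.raises(ValueError):
        fit_sphere(planar)
    with pytest.raises(ValueError):
        fit_sphere(np.zeros((3, 3)))


def test_frame_axes_and_origin(coarse_frame):
    frame, mesh = coarse_frame
    assert frame.hip_joint_centre == pytest.approx(np.zeros(3))
    assert frame.shaft_axis == pytest.approx([0.0, 0.0, 1.0])
    assert frame.condylar_line == pytest.approx([1.0, 0.0, 0.0])
    # medial condyle on the medial (+x) side, knee inferior to the hip
    assert frame.condyle_medial[0] > frame.condyle_lateral[0]
    assert frame.knee_joint_centre[2] < -200.0
    assert np.linalg.norm(frame.mechanical_axis) == pytest.approx(1.0)
    # rotation is orthonormal and maps the original mesh onto the registered
    assert frame.rotation @ frame.rotation.T == pytest.approx(np.eye(3))
    # fitted head radius close to half the head diameter (51 mm default)
    assert frame.femoral_head_radius == pytest.approx(25.5, abs=1.0)


def test_frame_is_invariant_to_rigid_motion(coarse_femur):
    frame0, _ = compute_frame(coarse_femur)
    theta = 0.7
    R = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(theta), -np.sin(theta)],
            [0.0, np.sin(theta), np.cos(theta)],
        ]
    )
    moved = coarse_femur.transformed(R, np.array([100.0, -40.0, 12.0]))
    frame1, _ = compute_frame(moved)
    assert frame1.knee_joint_centre == pytest.approx(frame0.knee_joint_centre, abs=1e-6)
    assert frame1.condyle_medial == pytest.approx(frame0.condyle_medial, abs=1e-6)
    assert frame1.femoral_head_radius == pytest.approx(frame0.femoral_head_radius)


def test_frame_handles_mirrored_side(coarse_femur):
    # a right femur is the mirror image of a left one; medial must stay +x
    frame0, _ = compute_frame(coarse_femur)
    frame1, _ = compute_frame(coarse_femur.mirrored(axis=0))
    assert frame1.condyle_medial[0] > 0
    assert frame1.condyle_medial[0] == pytest.approx(frame0.condyle_medial[0], abs=1e-6)


def test_kmeans_stations_ordered_and_deterministic(coarse_frame):
    frame, mesh = coarse_frame
    a = kmeans_regions(mesh, frame, seed=1)
    b = kmeans_regions(mesh, frame, seed=1)
    assert np.array_equal(a.labels, b.labels)
    assert np.allclose(a.stations, b.stations)
    z = a.stations[:, 2]
    assert z[0] > z[1] > z[2]  # proximal -> mid -> distal
    # stations live between the joints, not in them
    assert z.max() < -0.5 * frame.femoral_head_radius
    assert z.min() > frame.knee_joint_centre[2]
    assert a.station_names == ("proximal", "mid", "distal")
    # every diaphyseal node has a station, joint nodes have none
    assert set(np.unique(a.diaphysis_labels)) == {-1, 0, 1, 2}
    head = mesh.node_sets["head"]
    assert np.bincount(a.diaphysis_labels[head] + 1).argmax() == 0


def test_frame_to_json(tmp_path, coarse_frame):
    frame, _ = coarse_frame
    path = tmp_path / "frame.json"
    frame.to_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["shaft_axis"] == [0.0, 0.0, 1.0]
    assert len(data["rotation"]) == 3
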