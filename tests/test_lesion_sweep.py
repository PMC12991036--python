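"""Lesion placement, sweep paths, TCI and cortical-volume oracles on
structured tubes."""

import numpy as np
import pytest

from femursweep import (
    CORTICAL,
    AnatomicalFrame,
    LesionSpec,
    MaterialField,
    apply_lesion,
    build_path,
    compute_tci,
    cortical_volume_loss,
    detect_tci_case,
    select_lesion_elements,
)


def tube_frame():
    """Anatomical frame for the structured tube: shaft +z, medial +x."""
    return AnatomicalFrame(
        hip_joint_centre=np.array([0.0, 0.0, 120.0]),
        femoral_head_radius=25.0,
        knee_joint_centre=np.array([0.0, 0.0, -20.0]),
        shaft_axis=np.array([0.0, 0.0, 1.0]),
        neck_axis=np.array([1.0, 0.0, 0.0]),
        mechanical_axis=np.array([0.0, 0.0, -1.0]),
        condylar_line=np.array([1.0, 0.0, 0.0]),
        condyle_medial=np.array([20.0, 0.0, -20.0]),
        condyle_lateral=np.array([-20.0, 0.0, -20.0]),
    )


def test_build_path_extent_and_order(two_phase_tube):
    path = build_path(tube_frame(), np.array([0.0, 0.0, 50.0]), two_phase_tube,
                      step=1.0, diameter=10.0, station="mid")
    # outer radius 20, lesion radius 5: centres from +24 (medial) to -24
    assert path.offsets[0] == 24.0
    assert path.offsets[-1] == -24.0
    assert np.all(np.diff(path.offsets) == -1.0)  # medial -> lateral
    # the sphere pokes out of the outer surface beyond |offset| = 15
    assert np.array_equal(path.beyond_surface, np.abs(path.offsets) + 5.0 > 20.0)
    assert np.allclose(path.centres[:, 1], 0.0)
    assert np.allclose(path.centres[:, 2], 50.0)


def test_build_path_rejects_outside_station(two_phase_tube):
    with pytest.raises(ValueError):
        build_path(tube_frame(), np.array([0.0, 0.0, 500.0]), two_phase_tube)


def test_select_lesion_elements(two_phase_tube):
    centre = np.array([15.0, 0.0, 50.0])
    ids = select_lesion_elements(two_phase_tube, centre, 10.0)
    assert ids.size > 0
    d = np.linalg.norm(two_phase_tube.centroids[ids] - centre, axis=1)
    assert np.all(d <= 5.0)
    # the hollow core contains no elements
    empty = select_lesion_elements(two_phase_tube, np.array([0.0, 0.0, 50.0]), 10.0)
    assert empty.size == 0


def test_apply_lesion_copies_and_validates(two_phase_tube):
    n = two_phase_tube.n_elements
    mats = MaterialField(E=np.full(n, 1000.0), nu=0.3)
    ids = select_lesion_elements(two_phase_tube, np.array([15.0, 0.0, 50.0]), 10.0)
    spec = LesionSpec(centre=[15.0, 0.0, 50.0], element_ids=ids)
    lesioned = apply_lesion(mats, spec)
    assert np.all(lesioned.E[ids] == 0.05)
    assert np.all(mats.E == 1000.0)  # baseline untouched
    weak = MaterialField(E=np.full(n, 0.01), nu=0.3)
    with pytest.raises(ValueError):  # lesion stiffer than what it replaces
        apply_lesion(weak, spec)


def test_tci_oracle_on_tube(two_phase_tube):
    frame = tube_frame()
    # trabecular band is 10 <= r <= 12.5; lesion at x = 9.5 with radius 5
    # reaches x = 14.5, i.e. 2 mm past the interface at 12.5
    spec = LesionSpec(centre=[9.5, 0.0, 50.0], diameter=10.0)
    assert compute_tci(two_phase_tube, spec, frame) == pytest.approx(2.0)
    # fully trabecular-confined lesion: small sphere inside the band
    spec0 = LesionSpec(centre=[11.0, 0.0, 50.0], diameter=2.0)
    assert compute_tci(two_phase_tube, spec0, frame) == 0.0
    # penetration is capped at the lesion diameter
    deep = LesionSpec(centre=[25.0, 0.0, 50.0], diameter=10.0)
    assert compute_tci(two_phase_tube, deep, frame) == pytest.approx(10.0)
    # lateral-side symmetry
    lat = LesionSpec(centre=[-9.5, 0.0, 50.0], diameter=10.0)
    assert compute_tci(two_phase_tube, lat, frame) == pytest.approx(2.0)


def test_cortical_volume_loss_oracle(two_phase_tube):
    ids = select_lesion_elements(two_phase_tube, np.array([14.0, 0.0, 50.0]), 10.0)
    spec = LesionSpec(centre=[14.0, 0.0, 50.0], element_ids=ids)
    got = cortical_volume_loss(two_phase_tube, spec)
    cort_ids = ids[two_phase_tube.region_label[ids] == CORTICAL]
    assert got == pytest.approx(two_phase_tube.volumes[cort_ids].sum())
    assert 0 < got < two_phase_tube.volumes[ids].sum()
    # lesion confined to the trabecular band destroys no cortex
    ids0 = select_lesion_elements(two_phase_tube, np.array([11.0, 0.0, 50.0]), 2.0)
    spec0 = LesionSpec(centre=[11.0, 0.0, 50.0], diameter=2.0, element_ids=ids0)
    assert cortical_volume_loss(two_phase_tube, spec0) == 0.0


def test_cortical_volume_loss_requires_labels(two_phase_tube):
    from femursweep import make_box_mesh

    box = make_box_mesh(10.0, 10.0, 10.0)
    spec = LesionSpec(centre=[5.0, 5.0, 5.0], element_ids=np.array([0]))
    with pytest.raises(ValueError):
        cortical_volume_loss(box, spec)


def test_detect_tci_case():
    losses = [0.0, 0.0, 0.0, 2.0, 5.0, 9.0, 14.0]
    assert detect_tci_case(losses, target_mm=3) == 5
    assert detect_tci_case(losses, target_mm=1) == 3
    with pytest.raises(ValueError):  # flat series: never enters the cortex
        detect_tci_case([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):  # not enough increasing records
        detect_tci_case([0.0, 0.0, 2.0], target_mm=3)


def test_lesion_spec_validation():
    with pytest.raises(ValueError):
        LesionSpec(centre=[0, 0, 0], diameter=-1.0)
    with pytest.raises(ValueError):
        LesionSpec(centre=[0, 0, 0], lesion_modulus=0.0)
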