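"""Synthetic femur generator and synthetic HU image with phantoms."""

import dataclasses

import numpy as np
import pytest

from femursweep import (
    CORTICAL,
    FemurParams,
    VoxelImage,
    fit_hu_density,
    generate_femur,
    measure_diaphyseal_diameter,
    measure_head_diameter,
    measure_shaft_length,
    sample_phantom_hu,
    synthesize_hu_image,
)


def test_generated_mesh_is_sound(coarse_femur):
    assert coarse_femur.n_connected_components() == 1
    assert np.all(coarse_femur.signed_volumes() > 0)
    for key in ("head", "medial_condyle", "lateral_condyle"):
        assert len(coarse_femur.node_sets[key]) >= 10
    assert set(np.unique(coarse_femur.region_label)) <= {0, 1}
    assert (coarse_femur.region_label == CORTICAL).any()
    assert (coarse_femur.region_label != CORTICAL).any()


def test_generated_dimensions_match_parameters(coarse_params, coarse_femur):
    head = measure_head_diameter(coarse_femur)
    assert head == pytest.approx(coarse_params.head_diameter, rel=0.05)
    # wider slab at coarse sampling: surface rings sit ~4 mm apart
    dia = measure_diaphyseal_diameter(coarse_femur, slab_halfwidth=5.0)
    assert dia == pytest.approx(coarse_params.diaphyseal_outer_diameter, rel=0.08)
    length = measure_shaft_length(coarse_femur)
    assert length == pytest.approx(coarse_params.shaft_length, rel=0.10)


def test_generator_is_deterministic(coarse_params):
    a = generate_femur(coarse_params)
    b = generate_femur(coarse_params)
    assert np.array_equal(a.nodes, b.nodes)
    assert np.array_equal(a.tets, b.tets)
    assert np.array_equal(a.region_label, b.region_label)


def test_params_validation():
    with pytest.raises(ValueError):
        FemurParams(neck_shaft_angle=200.0).validate()
    with pytest.raises(ValueError):
        FemurParams(grid_spacing=-1.0).validate()
    with pytest.raises(ValueError):
        FemurParams.from_dict({"shaft_length": 400.0})  # seed is mandatory


def test_synthetic_image_recovers_calibration(tmp_path, coarse_params):
    params = dataclasses.replace(coarse_params, material_mode="heterogeneous",
                                 grid_spacing=10.0)
    mesh = generate_femur(params)
    true_fit = fit_hu_density([25.0, 125.0, 245.0], [0.0, 0.075, 0.150])
    image = synthesize_hu_image(mesh, true_fit, noise_sd=0.0,
                                spacing=(2.0, 2.0, 2.0))
    pairs = sample_phantom_hu(image)
    densities = [d for d, _ in pairs]
    hu_means = [h for _, h in pairs]
    assert densities == [0.0, 0.075, 0.150]
    recovered = fit_hu_density(hu_means, densities)
    # noiseless phantoms reproduce the ground-truth line almost exactly
    # HU voxels are stored as float32; tolerances reflect that precision
    assert recovered.b == pytest.approx(true_fit.b, rel=1e-5)
    assert recovered.a == pytest.approx(true_fit.a, abs=1e-6)
    assert recovered.r_squared == pytest.approx(1.0, abs=1e-9)

    # trilinear sampling at element centroids gives bone-like HU inside
    hu_c = image.sample(mesh.centroids)
    assert np.isfinite(hu_c).all()
    assert hu_c.max() > 500.0  # cortical bone is bright

    # image round trip
    base = str(tmp_path / "img")
    image.save(base)
    back = VoxelImage.load(base)
    assert np.allclose(back.hu, image.hu)
    assert back.spacing == image.spacing
    assert len(back.phantom_rois) == 3


def test_two_phase_mesh_rejects_image_synthesis(coarse_femur):
    true_fit = fit_hu_density([25.0, 125.0, 245.0], [0.0, 0.075, 0.150])
    with pytest.raises(ValueError):
        synthesize_hu_image(coarse_femur, true_fit)
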