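"""Strain-rate tensors: shape fit, domain decomposition, accumulation."""

import numpy as np
import pytest

from epitect.strain2d import (
    accumulate_strain,
    domain_strain_decomposition,
    shape_tensor,
)
from epitect.synthetic import generate_fixture
from epitect.tracking_io import build_adjacency_over

CENTRE = 13  # middle cell of the 5x5 hex fixtures


def test_shape_tensor_of_circle_is_radius_times_identity():
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    circle = np.column_stack([2 * np.cos(t), 2 * np.sin(t)])
    np.testing.assert_allclose(shape_tensor(circle), 2 * np.eye(2), atol=2e-4)


def test_shape_tensor_of_rectangle():
    rect = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float)
    w = np.linalg.eigvalsh(shape_tensor(rect))
    np.testing.assert_allclose(w, [2 / np.sqrt(3), 4 / np.sqrt(3)], rtol=1e-12)


def test_shape_tensor_rotation_equivariance():
    rect = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float)
    th = np.radians(30)
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    q = shape_tensor(rect @ r.T)
    w, v = np.linalg.eigh(q)
    np.testing.assert_allclose(w, [2 / np.sqrt(3), 4 / np.sqrt(3)], rtol=1e-10)
    major = v[:, 1]
    assert abs(abs(major @ np.array([np.cos(th), np.sin(th)])) - 1) < 1e-10


def test_degenerate_polygon_raises():
    with pytest.raises(ValueError):
        shape_tensor(np.array([[0, 0], [1, 0], [2, 0]], float))


def _decompose(fx, frame=1):
    adjacency = build_adjacency_over(fx["cells"], "apical")
    return domain_strain_decomposition(fx["cells"], adjacency, CENTRE, frame, "apical", fx["dt"])


def test_affine_flow_oracle_tissue_equals_sym_L():
    L = np.array([[0.01, 0.003], [0.003, -0.01]])
    res = _decompose(generate_fixture("affine_flow", L=L, n_frames=3, dt=2.0))
    assert res.valid
    assert np.abs(res.tissue - (L + L.T) / 2).max() < 1e-6
    assert np.abs(res.intercalation).max() < 1e-6


def test_rigid_rotation_carries_no_strain():
    res = _decompose(generate_fixture("affine_flow", L=np.zeros((2, 2)),
                                      omega_deg_min=5.0, n_frames=3, dt=2.0))
    assert res.valid
    assert np.abs(res.tissue).max() < 1e-9
    assert np.abs(res.cell_shape).max() < 1e-9
    assert res.rotation_deg == pytest.approx(5.0, abs=1e-9)


def test_pure_shape_change_has_no_intercalation():
    # isotropic + deviatoric exponential flow advecting shapes and centroids
    L = np.diag([0.012, -0.008])
    res = _decompose(generate_fixture("affine_flow", L=L, n_frames=3, dt=2.0))
    assert res.valid
    assert np.abs(res.intercalation).max() < 1e-3


def test_frozen_shapes_sliding_is_pure_intercalation():
    fx = generate_fixture("shear_frozen", gamma_per_min=0.02, n_frames=3, dt=2.0)
    res = _decompose(fx)
    assert res.valid
    assert np.abs(res.cell_shape).max() < 1e-3
    np.testing.assert_allclose(res.intercalation, res.tissue, atol=1e-12)
    np.testing.assert_allclose(res.tissue, fx["tissue_truth"], atol=2e-4)


def test_additive_decomposition_is_exact_by_construction(placode):
    frames = [5, 10]
    for f in frames:
        for cid in list(placode.truth.matches)[:10]:
            res = domain_strain_decomposition(placode.cells, placode.adjacency, cid, f,
                                              "apical", placode.meta.frame_interval_min)
            if res.valid:
                np.testing.assert_allclose(
                    res.intercalation, res.tissue - res.cell_shape, atol=1e-15)
                np.testing.assert_allclose(res.tissue, res.tissue.T, atol=1e-15)


def test_global_translation_leaves_strain_unchanged():
    fx = generate_fixture("shear_frozen", gamma_per_min=0.02, n_frames=3, dt=2.0)
    res0 = _decompose(fx)
    moved = fx["cells"].copy()
    moved["polygon"] = [p + np.array([7.0, -3.0]) for p in moved["polygon"]]
    moved["x"] += 7.0
    moved["y"] -= 3.0
    adjacency = build_adjacency_over(moved, "apical")
    res1 = domain_strain_decomposition(moved, adjacency, CENTRE, 1, "apical", fx["dt"])
    np.testing.assert_allclose(res1.tissue, res0.tissue, atol=1e-9)
    np.testing.assert_allclose(res1.cell_shape, res0.cell_shape, atol=1e-9)


def test_under_determined_domain_is_flagged_invalid():
    fx = generate_fixture("shear_frozen", n_frames=3)
    cells = fx["cells"]
    # keep only the focal cell and one neighbour
    keep = cells["cell_id"].isin([CENTRE, CENTRE + 1])
    adjacency = build_adjacency_over(cells[keep], "apical")
    res = domain_strain_decomposition(cells[keep], adjacency, CENTRE, 1, "apical", 2.0)
    assert not res.valid


def test_end_of_movie_windows_are_flagged():
    fx = generate_fixture("affine_flow", L=np.diag([0.01, -0.01]), n_frames=3, dt=2.0)
    adjacency = build_adjacency_over(fx["cells"], "apical")
    res = domain_strain_decomposition(fx["cells"], adjacency, CENTRE, 0, "apical", 2.0)
    assert res.valid and res.flag == "end window"


def test_accumulated_strain_of_constant_rate():
    ratio, gaps = accumulate_strain([0.0025] * 36, 1.0)
    assert round(float(ratio[-1]), 2) == 1.09
    assert not gaps.any()


def test_accumulated_strain_of_zero_and_reversing_rates():
    ratio, _ = accumulate_strain([0.0] * 10, 2.0)
    np.testing.assert_allclose(ratio, 1.0)
    ratio, _ = accumulate_strain([0.01] * 5 + [-0.01] * 5, 2.0)
    assert ratio[-1] == pytest.approx(1.0)


def test_gaps_are_excluded_and_flagged():
    ratio, gaps = accumulate_strain([0.01, np.nan, 0.01], 1.0)
    assert gaps.tolist() == [False, True, False]
    assert ratio[-1] == pytest.approx(np.exp(0.02))
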