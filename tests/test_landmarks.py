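import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clearspeech.landmarks import (
    CHIN,
    NORMALIZED,
    NOSE_TIP,
    PIXEL,
    InvalidGeometryError,
    LandmarkFrame,
    NormalizationParams,
    VisualCues,
    compute_visual_cues,
    denormalize_frame,
    normalize_frame,
)
from clearspeech.synthetic import face_frame


def test_frame_shape_and_indexing():
    frame = face_frame()
    assert frame.points.shape == (68, 2)
    np.testing.assert_allclose(frame.landmark(NOSE_TIP), [0.0, 0.0])
    with pytest.raises(IndexError):
        frame.landmark(0)
    with pytest.raises(IndexError):
        frame.landmark(69)
    with pytest.raises(ValueError):
        LandmarkFrame(np.zeros((67, 2)))
    with pytest.raises(ValueError):
        LandmarkFrame(np.full((68, 2), np.nan))


def test_normalization_convention():
    pix = denormalize_frame(
        face_frame(), NormalizationParams(np.array([120.0, 90.0]), 0.6, 40.0)
    )
    norm, params = normalize_frame(pix)
    assert norm.space == NORMALIZED
    np.testing.assert_allclose(norm.nose_tip, [0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(norm.eye_midpoint, [0.0, 1.0], atol=1e-12)
    assert params.scale == pytest.approx(40.0)


def test_normalize_is_idempotent_on_normalized_frames():
    frame = face_frame(0.4, 0.8, 1.7)
    norm, params = normalize_frame(frame)
    np.testing.assert_allclose(norm.points, frame.points, atol=1e-12)
    np.testing.assert_allclose(params.translation, [0.0, 0.0], atol=1e-12)
    assert params.scale == pytest.approx(1.0)
    assert abs(math.remainder(params.rotation, 2 * math.pi)) < 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    tx=st.floats(-500, 500),
    ty=st.floats(-500, 500),
    rot=st.floats(-math.pi, math.pi),
    scale=st.floats(0.05, 50.0),
)
def test_round_trip_property(tx, ty, rot, scale):
    template = face_frame(0.35, 0.9, 1.6)
    params = NormalizationParams(np.array([tx, ty]), rot, scale)
    pix = denormalize_frame(template, params)
    assert pix.space == PIXEL
    norm, rec = normalize_frame(pix)
    np.testing.assert_allclose(norm.points, template.points, atol=1e-8)
    back = denormalize_frame(norm, rec)
    np.testing.assert_allclose(back.points, pix.points, atol=1e-6 * max(1.0, scale))


def test_cues_invariant_under_similarity(rng):
    template = face_frame(0.5, 0.86, 1.88)
    base = compute_visual_cues(template).as_array()
    for _ in range(10):
        params = NormalizationParams(
            rng.uniform(-200, 200, 2), rng.uniform(-3, 3), rng.uniform(0.2, 30)
        )
        norm, _ = normalize_frame(denormalize_frame(template, params))
        np.testing.assert_allclose(compute_visual_cues(norm).as_array(), base, atol=1e-9)


def test_degenerate_geometry_raises():
    pts = face_frame().points.copy()
    pts[36:48] = pts[NOSE_TIP - 1]  # eye midpoint collapses onto the nose tip
    with pytest.raises(InvalidGeometryError):
        normalize_frame(LandmarkFrame(pts, PIXEL))
    with pytest.raises(InvalidGeometryError):
        NormalizationParams(np.zeros(2), 0.0, 0.0)
    with pytest.raises(InvalidGeometryError):
        NormalizationParams(np.zeros(2), 0.0, -2.0)


def test_cue_values_match_construction():
    v, h, jaw = 0.42, 0.80, 1.75
    cues = compute_visual_cues(face_frame(v, h, jaw))
    assert cues.v_stretch == pytest.approx(v, abs=1e-12)
    assert cues.h_stretch == pytest.approx(h, abs=1e-12)
    assert cues.jaw_lowering == pytest.approx(jaw, abs=1e-12)
    assert cues.eccentricity == pytest.approx(math.sqrt(1 - v / h), abs=1e-12)
    assert cues.area == pytest.approx(math.pi / 4 * v * h, abs=1e-12)


def test_eccentricity_limits_exact():
    # V = H exactly: place lip-mid and mouth-corner landmarks symmetrically
    pts = face_frame(0.3, 0.8, 1.6).points.copy()
    center = np.array([0.0, -1.0])
    pts[51] = center + [0.0, 0.25]  # l52 upper lip mid
    pts[57] = center - [0.0, 0.25]  # l58 lower lip mid
    pts[48] = center - [0.25, 0.0]  # l49 left corner
    pts[54] = center + [0.25, 0.0]  # l55 right corner
    round_lips = compute_visual_cues(LandmarkFrame(pts, NORMALIZED))
    assert round_lips.v_stretch == round_lips.h_stretch
    assert round_lips.eccentricity == 0.0

    closed = compute_visual_cues(face_frame(0.0, 0.7, 1.5))
    assert closed.v_stretch == 0.0
    assert closed.eccentricity == 1.0
    fully_closed = compute_visual_cues(face_frame(0.0, 0.0, 1.5))
    assert fully_closed.eccentricity == 1.0  # defined limit when both axes vanish
    assert fully_closed.area == 0.0


def test_eccentricity_symmetric_in_axes():
    a = compute_visual_cues(face_frame(0.3, 0.8, 1.6))
    b = compute_visual_cues(face_frame(0.8, 0.3, 1.6))
    assert a.eccentricity == pytest.approx(b.eccentricity, abs=1e-12)
    assert a.area == pytest.approx(b.area, abs=1e-12)


def test_cue_scaling_law():
    # scaling a normalized frame by k scales lengths by k and area by k^2
    frame = face_frame(0.4, 0.9, 1.7)
    k = 1.7
    scaled = LandmarkFrame(frame.points * k, NORMALIZED)
    c1 = compute_visual_cues(frame)
    c2 = compute_visual_cues(scaled)
    assert c2.v_stretch == pytest.approx(k * c1.v_stretch)
    assert c2.jaw_lowering == pytest.approx(k * c1.jaw_lowering)
    assert c2.area == pytest.approx(k**2 * c1.area)
    assert c2.eccentricity == pytest.approx(c1.eccentricity)


def test_visual_cues_validation():
    with pytest.raises(ValueError):
        VisualCues(-0.1, 0.5, 1.5, 0.5, 0.1)
    with pytest.raises(ValueError):
        VisualCues(0.1, 0.5, 1.5, 1.5, 0.1)
    cues = VisualCues(0.3, 0.5, 1.5, 0.5, 0.1)
    assert cues.minor_axis == 0.3 and cues.major_axis == 0.5


def test_cues_require_normalized_space():
    pix = denormalize_frame(face_frame(), NormalizationParams(np.zeros(2), 0.0, 50.0))
    with pytest.raises(ValueError):
        compute_visual_cues(pix)


def test_chin_is_jaw_midpoint():
    frame = face_frame(0.3, 0.8, 1.8)
    # jaw lowering is the chin-to-nose distance by construction
    assert np.linalg.norm(frame.landmark(CHIN)) == pytest.approx(1.8, abs=1e-12)
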