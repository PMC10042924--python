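import dataclasses

import numpy as np
import pytest
from numpy.polynomial import polynomial as npoly

from clearspeech.landmarks import NORMALIZED, LandmarkFrame, compute_visual_cues
from clearspeech.style_transfer import (
    ANCHOR_EPS,
    AVERAGE,
    SAME_TALKER,
    ChangeField,
    FoldWarning,
    ModificationConfig,
    average_change_fields,
    compute_change_field,
    has_fold,
    make_destination_frames,
    spatial_smooth_folds,
)
from clearspeech.synthetic import face_frame, synth_trajectory
from clearspeech.trajectory import CLEAR, PLAIN

from conftest import noiseless_talker

# flat coordinate index of the lower-lip-mid (l58) y coordinate
L58_Y = (58 - 1) * 2 + 1


def _offset_clear(plain, coord, offset):
    """Clear twin of a plain trajectory with one coordinate shifted by ``offset``."""
    frames = []
    for f in plain.frames:
        pts = f.points.copy()
        pts.reshape(-1)[coord] += offset
        frames.append(LandmarkFrame(pts, NORMALIZED))
    return plain.with_frames(frames, style=CLEAR)


def test_identical_pair_gives_zero_change(pair):
    plain, _ = pair
    clear_twin = plain.with_frames([f.copy() for f in plain.frames], style=CLEAR)
    field = compute_change_field(plain, clear_twin)
    assert field.delta_frames == 0.0
    np.testing.assert_allclose(field.relative_change, 0.0, atol=1e-9)
    np.testing.assert_allclose(field.additive_change, 0.0, atol=1e-9)


def test_delta_frames_and_metadata(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    assert field.delta_frames == 3.0  # 12 clear - 9 plain frames
    assert field.target_mode == SAME_TALKER
    assert field.n_pairs == 1
    assert field.word == "cod"


def test_stored_relative_change_value(pair):
    plain, _ = pair
    m = plain.mid_vowel_frame.points.reshape(-1)[L58_Y]
    clear = _offset_clear(plain, L58_Y, 0.25 * m)
    field = compute_change_field(plain, clear)
    t_mid = plain.mid_vowel_index / (plain.n_frames - 1)
    stored = npoly.polyval(t_mid, field.relative_change[:, L58_Y])
    assert stored == pytest.approx(0.25, abs=1e-9)


def test_compute_change_field_input_validation(pair):
    plain, clear = pair
    with pytest.raises(ValueError):
        compute_change_field(plain, dataclasses.replace(clear, word="kid"))
    with pytest.raises(ValueError):
        compute_change_field(dataclasses.replace(plain, vowel_span=None), clear)


def test_near_zero_anchor_uses_additive_channel(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    m = plain.mid_vowel_frame.points.reshape(-1)
    np.testing.assert_array_equal(field.fallback, np.abs(m) < ANCHOR_EPS)
    assert field.fallback.any()  # the nose tip sits at the origin
    # ratio channels are zeroed where the additive channel takes over
    np.testing.assert_array_equal(field.ratio_anim[:, field.fallback], 0.0)


def test_change_field_json_round_trip(tmp_path, pair):
    field = compute_change_field(*pair)
    p = tmp_path / "field.json"
    field.save(p)
    loaded = ChangeField.load(p)
    for name in ("ratio_anim", "relative_change", "additive_anim", "additive_change",
                 "reference_mid"):
        np.testing.assert_array_equal(getattr(loaded, name), getattr(field, name))
    np.testing.assert_array_equal(loaded.fallback, field.fallback)
    assert (loaded.word, loaded.n_pairs, loaded.delta_frames) == (
        field.word, field.n_pairs, field.delta_frames)


def test_average_of_single_field_is_identity(pair):
    field = compute_change_field(*pair)
    avg = average_change_fields([field])
    assert avg.target_mode == AVERAGE
    assert avg.n_pairs == 1
    np.testing.assert_allclose(avg.relative_change, field.relative_change, atol=1e-12)
    np.testing.assert_allclose(avg.delta_frames, field.delta_frames)


def test_average_of_opposite_fields_cancels(pair):
    plain, _ = pair
    m = plain.mid_vowel_frame.points.reshape(-1)[L58_Y]
    up = compute_change_field(plain, _offset_clear(plain, L58_Y, 0.2 * m))
    down = compute_change_field(plain, _offset_clear(plain, L58_Y, -0.2 * m))
    avg = average_change_fields([up, down])
    assert avg.n_pairs == 2
    np.testing.assert_allclose(avg.relative_change, 0.0, atol=1e-9)
    np.testing.assert_allclose(avg.additive_change, 0.0, atol=1e-9)


def test_average_matches_brute_force_mean(rng, pair):
    fields = []
    template = compute_change_field(*pair)
    for _ in range(5):
        fields.append(
            dataclasses.replace(
                template,
                relative_change=template.relative_change
                + rng.normal(0, 0.02, template.relative_change.shape),
                delta_frames=float(rng.integers(1, 5)),
            )
        )
    avg = average_change_fields(fields)
    t = np.linspace(0.0, 1.0, 11)
    brute = np.mean([npoly.polyval(t, f.relative_change) for f in fields], axis=0)
    keep = ~avg.fallback  # ratio channels are zeroed on fallback coordinates
    np.testing.assert_allclose(
        npoly.polyval(t, avg.relative_change)[keep], brute[keep], atol=1e-10
    )
    assert avg.delta_frames == pytest.approx(np.mean([f.delta_frames for f in fields]))


def test_average_rejects_bad_input(pair):
    field = compute_change_field(*pair)
    with pytest.raises(ValueError):
        average_change_fields([])
    with pytest.raises(ValueError):
        average_change_fields([field, dataclasses.replace(field, word="kid")])


def test_df_identity_at_zero(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    dest = make_destination_frames(plain, field, df=0.0)
    assert len(dest) == plain.n_frames
    # the noiseless synthetic motion is exactly degree 3, so the identity
    # limit reproduces the input landmarks themselves
    np.testing.assert_allclose(
        np.stack([f.points for f in dest]), plain.points(), atol=1e-9
    )


def test_df_worked_example_frames_and_change(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    assert len(make_destination_frames(plain, field, df=2.0)) == 15
    assert len(make_destination_frames(plain, field, df=1.0)) == 12

    m = plain.mid_vowel_frame.points.reshape(-1)[L58_Y]
    field25 = compute_change_field(plain, _offset_clear(plain, L58_Y, 0.25 * m))
    dest = make_destination_frames(plain, field25, df=2.0)
    mid = plain.mid_vowel_index
    applied = (dest[mid].points.reshape(-1)[L58_Y] - m) / m
    assert applied == pytest.approx(0.50, abs=1e-9)


def test_df_linearity():
    # equal-length pair so all dfs share one output time grid
    talker = noiseless_talker(n_plain_frames=10, n_clear_frames=10)
    plain = synth_trajectory(talker, "cod", PLAIN)
    clear = synth_trajectory(talker, "cod", CLEAR)
    field = compute_change_field(plain, clear)
    d0 = np.stack([f.points for f in make_destination_frames(plain, field, df=0.0)])
    d1 = np.stack([f.points for f in make_destination_frames(plain, field, df=1.0)])
    d3 = np.stack([f.points for f in make_destination_frames(plain, field, df=3.0)])
    np.testing.assert_allclose(d3 - d0, 3.0 * (d1 - d0), atol=1e-9)


def test_df_monotonic_exaggeration(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    peaks = []
    for df in (1.0, 2.0, 3.0):
        dest = make_destination_frames(plain, field, df=df)
        peaks.append(max(compute_visual_cues(f).v_stretch for f in dest))
    assert peaks[0] < peaks[1] < peaks[2]


def test_negative_df_rejected(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    with pytest.raises(ValueError):
        make_destination_frames(plain, field, df=-1.0)
    with pytest.raises(ValueError):
        ModificationConfig(df=0.0)


def test_word_mismatch_on_apply(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    with pytest.raises(ValueError):
        make_destination_frames(dataclasses.replace(plain, word="kid"), field)


# -- fold detection and correction --------------------------------------


def test_fold_predicate():
    clean = face_frame(0.4, 0.8, 1.7)
    assert not has_fold(clean)

    above_nose = clean.points.copy()
    above_nose[51, 1] = 0.05  # upper-lip mid above the nose tip (y-up)
    assert has_fold(LandmarkFrame(above_nose, NORMALIZED))

    crossed = clean.points.copy()
    crossed[65, 1] = crossed[63, 1] + 0.02  # inner lower lip above its pair
    assert has_fold(LandmarkFrame(crossed, NORMALIZED))


def test_fold_correction_resolves_and_contracts():
    clean = face_frame(0.4, 0.8, 1.7)
    pts = clean.points.copy()
    pts[51, 1] = 0.05
    folded = LandmarkFrame(pts, NORMALIZED)
    ring = slice(48, 60)
    before_dev = np.abs(pts[ring] - pts[ring].mean(axis=0)).max()

    out = spatial_smooth_folds([folded])[0]
    assert not has_fold(out)
    after_dev = np.abs(out.points[ring] - pts[ring].mean(axis=0)).max()
    assert after_dev <= before_dev + 1e-12  # smoothing contracts the excursion
    # non-lip landmarks are untouched
    np.testing.assert_array_equal(out.points[:48], pts[:48])


def test_fold_free_frames_pass_through(pair):
    plain, _ = pair
    out = spatial_smooth_folds(plain.frames)
    for a, b in zip(out, plain.frames):
        np.testing.assert_array_equal(a.points, b.points)


def test_unresolvable_fold_warns():
    pts = face_frame(0.4, 0.8, 1.7).points.copy()
    pts[48:68, 1] += 3.0  # whole mouth far above the nose: smoothing cannot fix it
    with pytest.warns(FoldWarning):
        out = spatial_smooth_folds([LandmarkFrame(pts, NORMALIZED)], max_iter=3)
    assert len(out) == 1


def test_self_reconstruction_recovers_clear_cues(pair):
    plain, clear = pair
    field = compute_change_field(plain, clear)
    dest = make_destination_frames(plain, field, df=1.0)
    assert len(dest) == clear.n_frames
    got = np.stack([compute_visual_cues(f).as_array() for f in dest])
    want = np.stack([compute_visual_cues(f).as_array() for f in clear.frames])
    plain_cues = np.stack([compute_visual_cues(f).as_array() for f in plain.frames])
    change = np.abs(want.max(axis=0) - plain_cues.max(axis=0))
    rms = np.sqrt(np.mean((got - want) ** 2, axis=0))
    assert np.all(rms < 0.05 * np.maximum(change, 1e-6))
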