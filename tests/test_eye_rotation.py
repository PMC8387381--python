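"""Rotation-vector math, camera correction and landmark reconstruction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from otoreflex import (CameraGeometry, OutOfModelError,
                       TorsionUnobservableError, axis_angle_components,
                       components_to_rotvec, correct_camera_axis,
                       reconstruct_rotation, series_reconstruct)
from otoreflex.eye_rotation import (LandmarkTrack, landmarks_from_directions,
                                    matrix_to_rotvec, reference_directions,
                                    rotvec_to_matrix)
from otoreflex.synthetic import project_landmarks

from conftest import zero_prefixed_series


def test_axis_angle_component_readout():
    assert np.allclose(axis_angle_components(np.zeros(3)), 0.0)
    r = np.array([np.tan(np.radians(15.0)), 0.0, 0.0])
    assert np.allclose(axis_angle_components(r), [30.0, 0.0, 0.0], atol=1e-12)
    r = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)  # |r| = 1 -> theta = 90 deg
    expected = 90.0 / np.sqrt(3.0)
    assert np.allclose(axis_angle_components(r), expected, atol=1e-9)


def test_axis_angle_round_trips_components():
    rng = np.random.default_rng(7)
    comps = rng.uniform(-40, 40, size=(200, 3))
    back = axis_angle_components(components_to_rotvec(comps))
    assert np.allclose(back, comps, atol=1e-10)


def test_total_angle_agrees_with_rotation_matrix_oracle():
    """2*atan(|n tan(theta/2)|) equals the angle extracted from the rotation
    matrix built independently from (axis, angle)."""
    rng = np.random.default_rng(11)
    for _ in range(300):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        theta = rng.uniform(1e-6, 90.0)
        r = axis * np.tan(np.radians(theta) / 2.0)
        # oracle: scipy builds the matrix from the standard rotation vector
        M = Rotation.from_rotvec(axis * np.radians(theta)).as_matrix()
        theta_oracle = np.degrees(
            np.arccos(np.clip((np.trace(M) - 1.0) / 2.0, -1.0, 1.0)))
        theta_r = 2.0 * np.degrees(np.arctan(np.linalg.norm(r)))
        assert theta_r == pytest.approx(theta_oracle, abs=1e-9 * max(1, theta))
        assert np.allclose(rotvec_to_matrix(r)[0], M, atol=1e-12)
        assert np.allclose(matrix_to_rotvec(M), r, atol=1e-12)


def test_camera_axis_correction():
    r = np.array([1.0, 0.0, 0.0])
    assert np.allclose(correct_camera_axis(r, 0.0, "left"), r)
    left = correct_camera_axis(r, 30.0, "left")
    right = correct_camera_axis(r, 30.0, "right")
    assert np.allclose(left, [np.cos(np.radians(30)), 0.5, 0.0], atol=1e-12)
    assert np.allclose(right, [np.cos(np.radians(30)), -0.5, 0.0], atol=1e-12)


def test_camera_correction_preserves_magnitude():
    rng = np.random.default_rng(3)
    r = rng.normal(size=(50, 3))
    for eye in ("left", "right"):
        out = correct_camera_axis(r, 30.0, eye)
        assert np.allclose(np.linalg.norm(out, axis=1),
                           np.linalg.norm(r, axis=1), atol=1e-12)


def test_reconstruct_project_identity_on_random_poses(geometry):
    """reconstruct(project(r)) = r within 0.1 deg for 1000 poses <= 60 deg."""
    rng = np.random.default_rng(1)
    n = 1000
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    comps = axes * rng.uniform(0.0, 60.0, n)[:, None]
    series = zero_prefixed_series(comps)
    track = project_landmarks(series, geometry, noise_px=0.0)
    rec = series_reconstruct(track, geometry)
    assert np.all(rec.valid)
    err = np.abs(rec.components_deg[120:] - comps).max()
    assert err < 0.1


def test_reconstruct_reference_frame_gives_zero(geometry):
    d_p, d_f = reference_directions(geometry)
    pupil = landmarks_from_directions(d_p, geometry)[0]
    freckle = landmarks_from_directions(d_f, geometry)[0]
    r = reconstruct_rotation(pupil, freckle, geometry, pupil, freckle)
    assert np.allclose(r.as_array(), 0.0, atol=1e-12)
    assert r.angle_deg == pytest.approx(0.0, abs=1e-9)


def test_pure_vertical_rotation_recovered(geometry):
    series = zero_prefixed_series(np.array([[0.0, 20.0, 0.0]]))
    track = project_landmarks(series, geometry, noise_px=0.0)
    # closed-form orthographic prediction: pupil moves by R*sin(20 deg)
    disp = np.hypot(*(track.pupil_xy[-1] - track.pupil_xy[0]))
    assert disp == pytest.approx(geometry.eye_radius_px * np.sin(np.radians(20.0)),
                                 abs=1e-9)
    rec = series_reconstruct(track, geometry)
    assert np.allclose(rec.components_deg[-1], [0.0, 20.0, 0.0], atol=0.1)


def test_composite_rotation_recovered(geometry):
    comps = np.array([[5.0, 10.0, -5.0]])
    track = project_landmarks(zero_prefixed_series(comps), geometry, noise_px=0.0)
    rec = series_reconstruct(track, geometry)
    assert np.allclose(rec.components_deg[-1], comps[0], atol=0.1)


def test_out_of_disc_frame_is_flagged_not_dropped(geometry):
    n = 150
    t = np.arange(n) / 240.0
    centre = np.array([geometry.eye_centre_x_px, geometry.eye_centre_y_px])
    pupil = np.tile(centre, (n, 1))
    d_f = reference_directions(geometry)[1]
    freckle = np.tile(landmarks_from_directions(d_f, geometry)[0], (n, 1))
    pupil[140] = centre + [2.0 * geometry.eye_radius_px, 0.0]  # leaves the disc
    track = LandmarkTrack(time=t, eye="left", pupil_xy=pupil, freckle_xy=freckle)
    rec = series_reconstruct(track, geometry)
    assert len(rec) == n
    assert list(rec.flagged_frames) == [140]
    assert np.isnan(rec.components_deg[140]).all()
    assert np.allclose(rec.components_deg[rec.valid], 0.0, atol=1e-9)


def test_single_frame_error_contracts(geometry):
    centre = np.array([geometry.eye_centre_x_px, geometry.eye_centre_y_px])
    d_f = reference_directions(geometry)[1]
    freckle = landmarks_from_directions(d_f, geometry)[0]
    with pytest.raises(OutOfModelError):
        reconstruct_rotation(centre + [500.0, 0.0], freckle, geometry, centre, freckle)
    with pytest.raises(TorsionUnobservableError):
        reconstruct_rotation(centre, centre, geometry, centre, centre)


def test_mirrored_eye_camera_correction_signs():
    """The same analysed rotation maps to opposite Y components once each
    eye's camera offset (mirrored about the midline) is corrected."""
    r = np.array([0.5, 0.0, 0.0])
    left = correct_camera_axis(r, 30.0, "left")
    right = correct_camera_axis(r, 30.0, "right")
    assert left[1] == pytest.approx(-right[1])
    assert left[0] == pytest.approx(right[0])
    assert left[2] == right[2] == 0.0
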