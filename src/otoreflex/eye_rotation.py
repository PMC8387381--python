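"""Rotation-vector representation and 3D reconstruction of eye position.

Eye position is encoded as a rotation vector r = n tan(theta/2): a rotation
by theta about the unit axis n, relative to the reference position (the eye
position while the animal is stationary).  The axis components are read out
as angles through the Euler-angle map theta = 2 atan(|r|): component i is
theta * r_i/|r|.  In head coordinates the X component is torsional, the Y
component vertical and the Z component horizontal eye position (the axes
are the interaural, naso-occipital and dorso-ventral head axes of the
recorded eye; left- and right-eye frames are mirrored).

Reconstruction model: the eye is a rigid sphere of known pixel radius
viewed by a distant camera along the camera axis, so the projection is
orthographic.  Two landmarks are tracked per frame: the pupil centre and an
iris freckle, both treated as points on the sphere surface.  The pupil
centre fixes the two non-torsional degrees of freedom and the freckle
bearing about the pupil axis fixes torsion.  Each frame's absolute
orientation is solved from the (pupil, freckle) direction pair by the
orthonormal-triad method, and the reported rotation is the relative
rotation from the reference frame — which makes reconstruction the exact
inverse of the forward projection for any pose facing the camera.

When the camera axis is offset from the interaural axis by a known angle
(30 degrees in the light-condition translation setup), the analysed
rotation vector is rotated about the Z axis into head coordinates: by
+angle for the left eye and -angle for the right eye.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import OutOfModelError, TorsionUnobservableError, ValidationError

__all__ = [
    "Eye", "CameraGeometry", "LandmarkTrack", "RotationVector", "EyeSeries",
    "axis_angle_components", "components_to_rotvec", "rotvec_to_matrix",
    "matrix_to_rotvec", "camera_correction_matrix", "correct_camera_axis",
    "reconstruct_rotation", "series_reconstruct", "directions_from_landmarks",
    "landmarks_from_directions", "reference_directions",
]


class Eye(str, enum.Enum):
    left = "left"
    right = "right"


@dataclass
class CameraGeometry:
    """Camera/eye geometry for one eye.

    camera_angle_deg : angle between the camera axis and the interaural
        axis (0 = camera directly beside the eye, the dark-condition setup;
        30 = the light-condition translation setup).
    eye_radius_px : radius of the eyeball sphere in image pixels.
    eye_centre_x_px, eye_centre_y_px : projection of the eyeball centre.
    freckle_offset_deg : angular distance of the iris freckle from the
        pupil centre on the eye sphere (used by the forward model; the
        reconstructor calibrates the freckle from the reference frame).
    freckle_bearing_deg : bearing of the freckle around the pupil axis at
        the reference position, 0 = along the image x axis.
    """

    camera_angle_deg: float = 0.0
    eye_radius_px: float = 120.0
    eye_centre_x_px: float = 160.0
    eye_centre_y_px: float = 120.0
    freckle_offset_deg: float = 25.0
    freckle_bearing_deg: float = 0.0

    def __post_init__(self):
        if self.eye_radius_px <= 0:
            raise ValidationError("eye_radius_px must be positive")
        if abs(self.camera_angle_deg) >= 90:
            raise ValidationError("|camera_angle_deg| must be < 90")


@dataclass
class LandmarkTrack:
    """Per-frame 2D camera coordinates of pupil centre and iris freckle."""

    time: np.ndarray
    eye: Eye
    pupil_xy: np.ndarray    # (N, 2) pixels
    freckle_xy: np.ndarray  # (N, 2) pixels

    def __post_init__(self):
        self.eye = Eye(self.eye)
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValidationError("LandmarkTrack time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class RotationVector:
    """Single rotation vector r = n tan(theta/2) with an eye tag."""

    rx: float
    ry: float
    rz: float
    eye: Eye = Eye.left

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    @property
    def angle_deg(self) -> float:
        return float(2.0 * np.degrees(np.arctan(np.linalg.norm(self.as_array()))))


@dataclass
class EyeSeries:
    """Time series of 3D eye positions for one eye.

    ``rotvec`` holds the (N, 3) rotation vectors, ``components_deg`` the
    (N, 3) torsional/vertical/horizontal axis-angle readout in degrees.
    Frames that could not be reconstructed are flagged in ``valid`` and set
    to NaN; they are never silently dropped.
    """

    time: np.ndarray
    eye: Eye
    rotvec: np.ndarray
    components_deg: np.ndarray
    valid: np.ndarray | None = None
    reference_note: str = "zero = stationary eye position"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eye = Eye(self.eye)
        if self.valid is None:
            self.valid = np.ones(self.time.size, dtype=bool)

    @property
    def torsional_deg(self) -> np.ndarray:
        return self.components_deg[:, 0]

    @property
    def vertical_deg(self) -> np.ndarray:
        return self.components_deg[:, 1]

    @property
    def horizontal_deg(self) -> np.ndarray:
        return self.components_deg[:, 2]

    @property
    def flagged_frames(self) -> np.ndarray:
        return np.nonzero(~self.valid)[0]

    def component(self, name: str) -> np.ndarray:
        return {"torsional": self.torsional_deg,
                "vertical": self.vertical_deg,
                "horizontal": self.horizontal_deg}[name]

    def __len__(self) -> int:
        return self.time.size


# ---------------------------------------------------------------------------
# axis-angle math
# ---------------------------------------------------------------------------


def axis_angle_components(r: np.ndarray) -> np.ndarray:
    """Axis-angle component readout in degrees.

    For r = n tan(theta/2) the total angle is theta = 2 atan(|r|) and the
    per-axis components are theta * r_i/|r| (all zero at |r| = 0).  Works on
    a single vector or an (N, 3) array.
    """
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    r2 = np.atleast_2d(r)
    mag = np.linalg.norm(r2, axis=1)
    theta = 2.0 * np.degrees(np.arctan(mag))
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(mag[:, None] > 0, theta[:, None] * r2 / mag[:, None], 0.0)
    comp = np.where(np.isfinite(comp), comp, 0.0)
    return comp[0] if single else comp


def components_to_rotvec(components_deg: np.ndarray) -> np.ndarray:
    """Inverse of :func:`axis_angle_components`."""
    c = np.asarray(components_deg, dtype=float)
    single = c.ndim == 1
    c2 = np.atleast_2d(c)
    theta = np.linalg.norm(c2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(theta[:, None] > 0, c2 / theta[:, None], 0.0)
    r = n * np.tan(np.radians(theta) / 2.0)[:, None]
    return r[0] if single else r


def rotvec_to_matrix(r: np.ndarray) -> np.ndarray:
    """Rotation matrices from tan-half-angle rotation vectors."""
    r = np.atleast_2d(np.asarray(r, dtype=float))
    quat = np.concatenate([r, np.ones((r.shape[0], 1))], axis=1)
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    M = Rotation.from_quat(quat).as_matrix()
    return M


def matrix_to_rotvec(M: np.ndarray) -> np.ndarray:
    """Tan-half-angle rotation vectors from rotation matrices (theta < 180)."""
    M = np.asarray(M, dtype=float)
    single = M.ndim == 2
    q = Rotation.from_matrix(M if not single else M[None]).as_quat()  # (x, y, z, w)
    sign = np.where(q[:, 3:4] < 0, -1.0, 1.0)
    q = q * sign
    with np.errstate(divide="ignore", invalid="ignore"):
        r = q[:, :3] / q[:, 3:4]
    return r[0] if single else r


def camera_correction_matrix(camera_angle_deg: float, eye: Eye | str) -> np.ndarray:
    """Rotation about Z taking camera-aligned coordinates to head
    coordinates: +angle for the left eye, -angle for the right eye."""
    a = np.radians(camera_angle_deg if Eye(eye) is Eye.left else -camera_angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def correct_camera_axis(r: np.ndarray, geometry: CameraGeometry | float,
                        eye: Eye | str) -> np.ndarray:
    """Rotate analysed rotation vector(s) from camera-aligned coordinates
    into head coordinates."""
    angle = geometry.camera_angle_deg if isinstance(geometry, CameraGeometry) else float(geometry)
    C = camera_correction_matrix(angle, eye)
    r = np.asarray(r, dtype=float)
    return r @ C.T


# ---------------------------------------------------------------------------
# spherical-eye orthographic projection
# ---------------------------------------------------------------------------
#
# Directions are unit vectors in the camera-aligned eye frame: x toward the
# camera, y along the image x axis, z along the image y axis.  A sphere
# surface point with direction d projects orthographically to
# centre + R * (d_y, d_z); it is visible while d_x > 0.


def directions_from_landmarks(xy: np.ndarray, geometry: CameraGeometry):
    """Unit sphere directions for image points; returns (dirs, inside_mask)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    u = (xy[:, 0] - geometry.eye_centre_x_px) / geometry.eye_radius_px
    v = (xy[:, 1] - geometry.eye_centre_y_px) / geometry.eye_radius_px
    s = u * u + v * v
    inside = s <= 1.0
    with np.errstate(invalid="ignore"):
        x = np.sqrt(np.clip(1.0 - s, 0.0, None))
    d = np.stack([x, u, v], axis=1)
    return d, inside


def landmarks_from_directions(d: np.ndarray, geometry: CameraGeometry) -> np.ndarray:
    """Orthographic image coordinates of sphere directions (inverse of
    :func:`directions_from_landmarks` on the front hemisphere)."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    x = geometry.eye_centre_x_px + geometry.eye_radius_px * d[:, 1]
    y = geometry.eye_centre_y_px + geometry.eye_radius_px * d[:, 2]
    return np.stack([x, y], axis=1)


def reference_directions(geometry: CameraGeometry):
    """Canonical reference pose: pupil on the camera axis, freckle at the
    configured angular offset and bearing."""
    delta = np.radians(geometry.freckle_offset_deg)
    psi = np.radians(geometry.freckle_bearing_deg)
    d_p = np.array([1.0, 0.0, 0.0])
    d_f = np.array([np.cos(delta), np.sin(delta) * np.cos(psi), np.sin(delta) * np.sin(psi)])
    return d_p, d_f


def _triads(d_p: np.ndarray, d_f: np.ndarray):
    """Orthonormal attitude triads from (pupil, freckle) direction pairs.

    Returns (N, 3, 3) matrices with columns (e1, e2, e3) and a mask of
    frames where the freckle direction is (numerically) parallel to the
    pupil direction, i.e. torsion is unobservable.
    """
    e1 = d_p
    w = d_f - np.sum(d_f * e1, axis=1, keepdims=True) * e1
    wn = np.linalg.norm(w, axis=1)
    degenerate = wn < 1e-9
    safe = np.where(degenerate[:, None], 1.0, wn[:, None])
    e2 = w / safe
    e3 = np.cross(e1, e2)
    B = np.stack([e1, e2, e3], axis=2)
    return B, degenerate


def _reconstruct_rotvecs(pupil_xy, freckle_xy, geometry, ref_pupil_xy, ref_freckle_xy):
    """Vectorized core: relative rotation vectors (camera frame) per frame."""
    d_p, in_p = directions_from_landmarks(pupil_xy, geometry)
    d_f, in_f = directions_from_landmarks(freckle_xy, geometry)
    d_p0, in_p0 = directions_from_landmarks(np.atleast_2d(ref_pupil_xy), geometry)
    d_f0, in_f0 = directions_from_landmarks(np.atleast_2d(ref_freckle_xy), geometry)
    if not (in_p0[0] and in_f0[0]):
        raise OutOfModelError("reference landmarks lie outside the projected eye disc")
    B0, deg0 = _triads(d_p0, d_f0)
    if deg0[0]:
        raise TorsionUnobservableError(
            "reference freckle coincides with the pupil centre; torsion is unobservable")
    B, degenerate = _triads(d_p, d_f)
    M = B @ B0[0].T
    r = matrix_to_rotvec(M)
    valid = in_p & in_f & ~degenerate
    r[~valid] = np.nan
    return r, valid, degenerate, in_p & in_f


def reconstruct_rotation(pupil_xy, freckle_xy, geometry: CameraGeometry,
                         ref_pupil_xy, ref_freckle_xy,
                         eye: Eye | str = Eye.left) -> RotationVector:
    """Reconstruct the rotation taking the reference eye pose to the
    current pose from a single landmark frame.

    Raises OutOfModelError if a landmark falls outside the projected eye
    disc, TorsionUnobservableError if the freckle coincides with the pupil
    centre.
    """
    r, valid, degenerate, inside = _reconstruct_rotvecs(
        np.atleast_2d(pupil_xy), np.atleast_2d(freckle_xy),
        geometry, ref_pupil_xy, ref_freckle_xy)
    if not inside[0]:
        raise OutOfModelError("landmark outside the projected eye disc")
    if degenerate[0]:
        raise TorsionUnobservableError(
            "freckle coincides with the pupil centre; torsion is unobservable")
    return RotationVector(*r[0], eye=Eye(eye))


def series_reconstruct(track: LandmarkTrack, geometry: CameraGeometry,
                       reference_window_s: float = 0.5,
                       camera_correct: bool = True) -> EyeSeries:
    """Reconstruct a full eye-position series from a landmark track.

    The reference (zero) position is the mean landmark geometry over the
    first ``reference_window_s`` seconds of the recording, which the
    protocols keep stationary.  Per frame: triad reconstruction ->
    camera-axis correction -> axis-angle component readout.  Frames whose
    landmarks leave the eye disc, lose the freckle, or exceed a 90-degree
    total rotation are flagged invalid (NaN), not dropped.
    """
    if len(track) == 0:
        raise ValidationError("empty landmark track")
    ref_mask = track.time < track.time[0] + reference_window_s
    if not ref_mask.any():
        ref_mask[0] = True
    ref_pupil = track.pupil_xy[ref_mask].mean(axis=0)
    ref_freckle = track.freckle_xy[ref_mask].mean(axis=0)

    r_cam, valid, _, _ = _reconstruct_rotvecs(
        track.pupil_xy, track.freckle_xy, geometry, ref_pupil, ref_freckle)

    # physiological range: total rotation beyond 90 deg is outside the model
    with np.errstate(invalid="ignore"):
        too_large = np.linalg.norm(r_cam, axis=1) > 1.0  # |r| = tan(theta/2) > tan(45)
    valid &= ~too_large
    r_cam[~valid] = np.nan

    r_head = correct_camera_axis(r_cam, geometry, track.eye) if camera_correct else r_cam
    comps = axis_angle_components(np.nan_to_num(r_head))
    comps[~valid] = np.nan
    return EyeSeries(
        time=np.array(track.time, copy=True), eye=track.eye, rotvec=r_head,
        components_deg=comps, valid=valid,
        reference_note=(f"zero = mean landmark pose over first "
                        f"{reference_window_s:g} s (stationary)"),
        meta={"camera_angle_deg": geometry.camera_angle_deg},
    )
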