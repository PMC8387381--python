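"""Synthetic binocular recordings with known reflex gains.

The generator emulates the statistical structure the analysis assumes: the
eye's vertical (and, in pitch-plane contexts, torsional and horizontal)
position tracks the instantaneous body-axis-to-GIA angle with a fixed gain
and a context-specific binocular sign pattern, and the landmarks observed
by the camera are the orthographic projection of that pose plus Gaussian
pixel noise.  Because the gains are known, every downstream stage — 3D
reconstruction, shift extraction, binocular combination, slope fitting —
can be tested by parameter recovery without any experimental recording.

Sign patterns (per-eye multiplier on gain * stimulus angle), chosen so the
binocular combination formulas return exactly gain * stimulus on noise-free
data:

===================  =========  =========  ==========
context              vertical   torsional  horizontal
===================  =========  =========  ==========
lateral_translation  (+1, -1)      --      (+1, +1)
roll_tilt            (+1, -1)      --      (+1, +1)
naso_translation     (+1, +1)   (+1, -1)   (+1, -1)
pitch_tilt           (+1, +1)   (+1, -1)   (+1, -1)
===================  =========  =========  ==========

Roll-plane vertical movement is disconjugate ("torsion-like"); pitch-plane
vertical movement enters the (L + R)/2 combination; the small horizontal
component is the conjugate "both eyes rotated slightly" movement of the
roll plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import __version__
from .errors import OutOfModelError, ValidationError
from .eye_rotation import (CameraGeometry, Eye, EyeSeries, LandmarkTrack,
                           axis_angle_components, camera_correction_matrix,
                           components_to_rotvec, landmarks_from_directions,
                           reference_directions, rotvec_to_matrix)
from .kinematics import GiaSeries, MotionProfile, TiltSchedule, stimulus_gia_angle
from .reflex import Context, context_for_stimulus

#: per-eye sign multipliers (left, right) per context and component
SIGN_PATTERNS: dict[Context, dict[str, tuple[int, int]]] = {
    Context.lateral_translation: {"vertical": (+1, -1), "torsional": (0, 0),
                                  "horizontal": (+1, +1)},
    Context.roll_tilt: {"vertical": (+1, -1), "torsional": (0, 0),
                        "horizontal": (+1, +1)},
    Context.naso_translation: {"vertical": (+1, +1), "torsional": (+1, -1),
                               "horizontal": (+1, -1)},
    Context.pitch_tilt: {"vertical": (+1, +1), "torsional": (+1, -1),
                         "horizontal": (+1, -1)},
}


@dataclass
class ReflexParams:
    """Generating parameters of the simulated reflex.

    Vertical gains default to the normal values of the index (0.297 for
    roll-plane/utricular contexts, 0.173 for pitch-plane/saccular
    contexts); the pitch-plane torsional gain is of the same order as the
    vertical one, and the horizontal gain is small (the "slight" conjugate
    rotation seen in roll-plane recordings; its true magnitude is not
    quantified, 0.02 is a documented placeholder).

    ``lag_tau_s`` adds an optional first-order low-pass between stimulus
    angle and eye position (default 0: the response is an instantaneous
    function of the GIA angle, as the recorded positions track the
    acceleration waveform).  ``quick_phase_span_deg`` > 0 adds sawtooth
    resetting to the horizontal component only.
    """

    gain_roll_vertical: float = 0.297
    gain_pitch_vertical: float = 0.173
    gain_pitch_torsional: float = 0.17
    gain_horizontal: float = 0.02
    landmark_noise_px: float = 0.5
    angle_noise_deg: float = 0.0
    gain_jitter_sd: float = 0.02
    lag_tau_s: float = 0.0
    quick_phase_span_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("gain_roll_vertical", "gain_pitch_vertical",
                     "gain_pitch_torsional", "gain_horizontal",
                     "landmark_noise_px", "angle_noise_deg", "gain_jitter_sd",
                     "lag_tau_s", "quick_phase_span_deg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def vertical_gain(self, context: Context) -> float:
        return (self.gain_roll_vertical if Context(context).plane == "roll"
                else self.gain_pitch_vertical)


@dataclass
class SimulatedExperiment:
    """One animal x one protocol, with every intermediate series."""

    animal_id: int
    stimulus: MotionProfile | TiltSchedule
    context: Context
    gia: GiaSeries
    eye_left: EyeSeries
    eye_right: EyeSeries
    track_left: LandmarkTrack
    track_right: LandmarkTrack
    params: ReflexParams
    manifest: dict = field(default_factory=dict)


def _first_order_lag(x: np.ndarray, tau_s: float, dt: float) -> np.ndarray:
    if tau_s <= 0:
        return x
    from scipy.signal import lfilter
    alpha = dt / (tau_s + dt)
    return lfilter([alpha], [1.0, alpha - 1.0], x, zi=[(1 - alpha) * x[0]])[0]


def simulate_reflex(stimulus, params: ReflexParams,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[EyeSeries, EyeSeries]:
    """Simulate both eyes' 3D position series for one stimulus.

    Each component of each eye is (sign) * gain * s(t), where s(t) is the
    body-axis-to-GIA angle in the plotted sign convention
    (:func:`otoreflex.kinematics.stimulus_gia_angle`): the response depends
    on the instantaneous GIA angle only, never on sled position.  Optional
    seeded Gaussian angle noise is added per sample, eye and component.
    """
    context = context_for_stimulus(stimulus)
    stim = stimulus_gia_angle(stimulus)
    s = stim.gia_deg
    dt = float(stim.time[1] - stim.time[0])
    s = _first_order_lag(s, params.lag_tau_s, dt)

    gains = {"vertical": params.vertical_gain(context),
             "torsional": params.gain_pitch_torsional,
             "horizontal": params.gain_horizontal}
    pattern = SIGN_PATTERNS[context]
    if rng is None:
        rng = np.random.default_rng(params.seed)

    series = []
    for i_eye, eye in enumerate((Eye.left, Eye.right)):
        comps = np.zeros((s.size, 3))
        for j, name in enumerate(("torsional", "vertical", "horizontal")):
            comps[:, j] = pattern[name][i_eye] * gains[name] * s
        if params.quick_phase_span_deg > 0:
            span = params.quick_phase_span_deg
            comps[:, 2] = np.mod(comps[:, 2] + span, 2 * span) - span
        if params.angle_noise_deg > 0:
            comps = comps + rng.normal(0.0, params.angle_noise_deg, comps.shape)
        series.append(EyeSeries(
            time=np.array(stim.time, copy=True), eye=eye,
            rotvec=components_to_rotvec(comps), components_deg=comps,
            meta={"context": context.value, "synthetic": True}))
    return series[0], series[1]


def project_landmarks(series: EyeSeries, geometry: CameraGeometry,
                      noise_px: float = 0.0,
                      rng: np.random.Generator | None = None) -> LandmarkTrack:
    """Project an eye series to pupil/freckle camera landmarks.

    The head-frame rotation vector is first carried back into
    camera-aligned coordinates (inverse of the camera-axis correction),
    then the reference pupil and freckle sphere points are rotated and
    projected orthographically; seeded Gaussian pixel noise is added last.
    Exact inverse of :func:`otoreflex.eye_rotation.series_reconstruct` at
    zero noise.  Raises OutOfModelError (with the sample index) if a pose
    turns a landmark away from the camera or exceeds 90 degrees total.
    """
    C_inv = camera_correction_matrix(geometry.camera_angle_deg, series.eye).T
    r_cam = series.rotvec @ C_inv.T
    mag = np.linalg.norm(r_cam, axis=1)
    if np.any(mag > 1.0):
        raise OutOfModelError(
            f"pose exceeds 90 deg total rotation at sample {int(np.argmax(mag > 1.0))}")
    M = rotvec_to_matrix(r_cam)
    d_p0, d_f0 = reference_directions(geometry)
    d_p = M @ d_p0
    d_f = M @ d_f0
    behind = (d_p[:, 0] <= 0) | (d_f[:, 0] <= 0)
    if np.any(behind):
        raise OutOfModelError(
            f"landmark rotated behind the eye sphere at sample {int(np.argmax(behind))}")
    pupil = landmarks_from_directions(d_p, geometry)
    freckle = landmarks_from_directions(d_f, geometry)
    if noise_px > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pupil = pupil + rng.normal(0.0, noise_px, pupil.shape)
        freckle = freckle + rng.normal(0.0, noise_px, freckle.shape)
    return LandmarkTrack(time=np.array(series.time, copy=True), eye=series.eye,
                         pupil_xy=pupil, freckle_xy=freckle)


def simulate_experiment(stimulus, params: ReflexParams, geometry: CameraGeometry,
                        rng: np.random.Generator, animal_id: int = 0,
                        ) -> SimulatedExperiment:
    """Simulate one animal on one protocol, through to camera landmarks."""
    from .kinematics import gia_tilt_angle, gia_angle_for_tilt
    left, right = simulate_reflex(stimulus, params, rng)
    track_l = project_landmarks(left, geometry, params.landmark_noise_px, rng)
    track_r = project_landmarks(right, geometry, params.landmark_noise_px, rng)
    gia = (gia_tilt_angle(stimulus) if isinstance(stimulus, MotionProfile)
           else gia_angle_for_tilt(stimulus))
    return SimulatedExperiment(
        animal_id=animal_id, stimulus=stimulus,
        context=context_for_stimulus(stimulus), gia=gia,
        eye_left=left, eye_right=right, track_left=track_l, track_right=track_r,
        params=params, manifest={})


def simulate_cohort(protocols, params: ReflexParams, n_animals: int, seed: int,
                    geometry: CameraGeometry | None = None,
                    ) -> list[SimulatedExperiment]:
    """Simulate a cohort of animals over a list of protocols.

    Every animal gets an independent, reproducible noise stream spawned
    from the master seed, and (if ``params.gain_jitter_sd`` > 0) its own
    vertical gains drawn around the population values to emulate
    between-animal variability.  The same (protocols, params, n_animals,
    seed) always regenerates bit-identical outputs.
    """
    if n_animals < 1:
        raise ValidationError("n_animals must be >= 1")
    if geometry is None:
        geometry = CameraGeometry()
    protocols = list(protocols)
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_animals)
    experiments: list[SimulatedExperiment] = []
    for animal in range(n_animals):
        rng = np.random.default_rng(children[animal])
        p = params
        if params.gain_jitter_sd > 0:
            jit_roll, jit_pitch = rng.normal(0.0, params.gain_jitter_sd, 2)
            p = replace(params,
                        gain_roll_vertical=max(0.0, params.gain_roll_vertical + jit_roll),
                        gain_pitch_vertical=max(0.0, params.gain_pitch_vertical + jit_pitch))
        for proto in protocols:
            exp = simulate_experiment(proto, p, geometry, rng, animal_id=animal)
            exp.manifest = {
                "seed": int(seed), "animal_id": animal,
                "spawn_key": [int(k) for k in children[animal].spawn_key],
                "otoreflex_version": __version__,
                "params": asdict(params),
                "geometry": asdict(geometry),
                "context": exp.context.value,
                "stimulus_meta": dict(exp.stimulus.meta),
            }
            experiments.append(exp)
    return experiments


def manifest_json(experiments: list[SimulatedExperiment]) -> str:
    """Cohort-level provenance manifest as canonical JSON."""
    return json.dumps([e.manifest for e in experiments], indent=2, sort_keys=True)
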