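"""Tabular file formats and run configuration.

All tabular exchange is plain CSV with fixed column names; floats are
written with 9 significant digits so a text round-trip preserves values.
Readers validate rather than coerce: a missing column, a non-monotone time
stamp or an empty file raises :class:`~otoreflex.errors.FormatError` naming
the offending column or row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .eye_rotation import CameraGeometry, Eye, EyeSeries, LandmarkTrack
from .kinematics import (GiaSeries, MotionProfile, TiltSchedule, TiltAxis,
                         TranslationAxis)
from .reflex import Context, ResponseTable

FLOAT_FMT = "%.9g"


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def _check_monotone(time: np.ndarray, path) -> None:
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        raise FormatError(f"{path}: time not strictly increasing at row {int(bad[0]) + 1}")


# ---------------------------------------------------------------------------
# kinematics series
# ---------------------------------------------------------------------------


def write_motion_profile_csv(profile: MotionProfile, path) -> None:
    df = pd.DataFrame({
        "time_s": profile.time, "position_mm": profile.position_mm,
        "velocity_mps": profile.velocity_mps, "accel_g": profile.accel_g,
        "leg_index": profile.leg_index, "axis": profile.axis.value,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_motion_profile_csv(path) -> MotionProfile:
    df = _read_csv(path)
    _require_columns(df, ["time_s", "position_mm", "velocity_mps", "accel_g",
                          "leg_index", "axis"], path)
    t = df["time_s"].to_numpy(float)
    _check_monotone(t, path)
    return MotionProfile(
        time=t, position_mm=df["position_mm"].to_numpy(float),
        velocity_mps=df["velocity_mps"].to_numpy(float),
        accel_g=df["accel_g"].to_numpy(float),
        axis=TranslationAxis(df["axis"].iloc[0]),
        leg_index=df["leg_index"].to_numpy(int))


def write_tilt_schedule_csv(schedule: TiltSchedule, path) -> None:
    df = pd.DataFrame({
        "time_s": schedule.time, "tilt_deg": schedule.tilt_deg,
        "plateau_index": schedule.plateau_index, "axis": schedule.axis.value,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tilt_schedule_csv(path) -> TiltSchedule:
    df = _read_csv(path)
    _require_columns(df, ["time_s", "tilt_deg", "plateau_index", "axis"], path)
    t = df["time_s"].to_numpy(float)
    _check_monotone(t, path)
    pidx = df["plateau_index"].to_numpy(int)
    tilt = df["tilt_deg"].to_numpy(float)
    n_plateaus = pidx.max() + 1
    levels = np.zeros(n_plateaus)
    for p in range(n_plateaus):
        m = pidx == p
        if not m.any():
            raise FormatError(f"{path}: plateau {p} has no samples")
        levels[p] = tilt[m][0]
    return TiltSchedule(time=t, tilt_deg=tilt, axis=TiltAxis(df["axis"].iloc[0]),
                        plateau_index=pidx, plateau_levels=levels)


def write_gia_csv(gia: GiaSeries, path) -> None:
    pd.DataFrame({"time_s": gia.time, "gia_deg": gia.gia_deg}).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_gia_csv(path) -> GiaSeries:
    df = _read_csv(path)
    _require_columns(df, ["time_s", "gia_deg"], path)
    t = df["time_s"].to_numpy(float)
    _check_monotone(t, path)
    return GiaSeries(t, df["gia_deg"].to_numpy(float))


def read_stimulus_csv(path):
    """Read a stimulus CSV, dispatching on its columns."""
    df = _read_csv(path)
    if "position_mm" in df.columns:
        return read_motion_profile_csv(path)
    if "tilt_deg" in df.columns:
        return read_tilt_schedule_csv(path)
    raise FormatError(f"{path}: neither a motion-profile nor a tilt-schedule CSV")


# ---------------------------------------------------------------------------
# eye series / landmarks
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ["time_s", "eye", "pupil_x_px", "pupil_y_px",
                    "freckle_x_px", "freckle_y_px"]


def write_landmark_csv(tracks, path) -> None:
    """Write one or more landmark tracks (e.g. the left/right pair)."""
    if isinstance(tracks, LandmarkTrack):
        tracks = [tracks]
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "time_s": tr.time, "eye": tr.eye.value,
            "pupil_x_px": tr.pupil_xy[:, 0], "pupil_y_px": tr.pupil_xy[:, 1],
            "freckle_x_px": tr.freckle_xy[:, 0], "freckle_y_px": tr.freckle_xy[:, 1],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_landmark_csv(path) -> dict[Eye, LandmarkTrack]:
    """Read landmark tracks; returns a dict keyed by eye."""
    df = _read_csv(path)
    _require_columns(df, LANDMARK_COLUMNS, path)
    out: dict[Eye, LandmarkTrack] = {}
    for eye_name, sub in df.groupby("eye", sort=True):
        try:
            eye = Eye(eye_name)
        except ValueError:
            raise FormatError(f"{path}: unknown eye label {eye_name!r}") from None
        t = sub["time_s"].to_numpy(float)
        _check_monotone(t, path)
        out[eye] = LandmarkTrack(
            time=t, eye=eye,
            pupil_xy=sub[["pupil_x_px", "pupil_y_px"]].to_numpy(float),
            freckle_xy=sub[["freckle_x_px", "freckle_y_px"]].to_numpy(float))
    return out


EYE_SERIES_COLUMNS = ["time_s", "eye", "rx", "ry", "rz",
                      "torsional_deg", "vertical_deg", "horizontal_deg"]


def write_eye_series_csv(series_list, path) -> None:
    if isinstance(series_list, EyeSeries):
        series_list = [series_list]
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "time_s": s.time, "eye": s.eye.value,
            "rx": s.rotvec[:, 0], "ry": s.rotvec[:, 1], "rz": s.rotvec[:, 2],
            "torsional_deg": s.torsional_deg, "vertical_deg": s.vertical_deg,
            "horizontal_deg": s.horizontal_deg,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_eye_series_csv(path) -> dict[Eye, EyeSeries]:
    df = _read_csv(path)
    _require_columns(df, EYE_SERIES_COLUMNS, path)
    out: dict[Eye, EyeSeries] = {}
    for eye_name, sub in df.groupby("eye", sort=True):
        t = sub["time_s"].to_numpy(float)
        _check_monotone(t, path)
        rot = sub[["rx", "ry", "rz"]].to_numpy(float)
        comps = sub[["torsional_deg", "vertical_deg", "horizontal_deg"]].to_numpy(float)
        out[Eye(eye_name)] = EyeSeries(
            time=t, eye=Eye(eye_name), rotvec=rot, components_deg=comps,
            valid=~np.isnan(comps).any(axis=1))
    return out


def write_response_table_csv(table: ResponseTable, path) -> None:
    table.data.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_response_table_csv(path) -> ResponseTable:
    df = _read_csv(path)
    _require_columns(df, ["context", "stimulus_deg", "mean_shift_deg",
                          "ci95_deg", "n"], path)
    context = Context(df["context"].iloc[0])
    return ResponseTable(df, context, n_animals=int(df["n"].max()))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: the five sled settings of the translation protocol: (a_max G, v_max m/s)
SLED_SETTINGS: tuple[tuple[float, float], ...] = (
    (0.2, 1.69), (0.3, 2.24), (0.7, 3.06), (0.9, 3.25), (1.3, 3.25))

_DEFAULT_CONFIG: dict = {
    "protocol": {
        "kind": "translation",
        "one_way_mm": 1800.0,
        "a_max_g": [a for a, _ in SLED_SETTINGS],
        "v_max_mps": [v for _, v in SLED_SETTINGS],
        "dwell_s": 0.3,
        "n_round_trips": 5,
        "rate_hz": 240.0,
        "axis": "interaural",
        "lead_in_s": 1.0,
    },
    "tilt": {
        "max_deg": 70.0,
        "step_deg": 10.0,
        "dwell_s": 5.0,
        "ramp_rate_dps": 4.0,
        "axis": "roll",
        "rate_hz": 60.0,
        "direction_order": "positive_first",
    },
    "geometry": {
        "camera_angle_deg": 0.0,
        "eye_radius_px": 120.0,
        "eye_centre_x_px": 160.0,
        "eye_centre_y_px": 120.0,
        "freckle_offset_deg": 25.0,
        "freckle_bearing_deg": 0.0,
    },
    "params": {
        "gain_roll_vertical": 0.297,
        "gain_pitch_vertical": 0.173,
        "gain_pitch_torsional": 0.17,
        "gain_horizontal": 0.02,
        "landmark_noise_px": 0.5,
        "angle_noise_deg": 0.0,
        "gain_jitter_sd": 0.02,
        "lag_tau_s": 0.0,
        "quick_phase_span_deg": 0.0,
        "seed": 0,
    },
    "analysis": {
        "window_legs": [3, 4],
        "component": "vertical",
        "mode": "peak_stimulus",
        "central_frac": 0.6,
        "through_origin": False,
        "reference_window_s": 0.5,
    },
    "run": {
        "n_animals": 10,
        "seed": 42,
        "plot": True,
        "log_level": "INFO",
    },
}

_AXIS_PAIRS = {"interaural": "roll", "naso_occipital": "pitch"}


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            out[key] = _merge_strict(dval, user.get(key, {}) or {}, f"{path}{key}.")
        else:
            out[key] = user.get(key, dval)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValidationError(f"unknown config key(s): "
                              f"{', '.join(sorted(path + k for k in unknown))}")
    return out


@dataclass
class RunConfig:
    """Validated end-to-end pipeline configuration."""

    protocol: dict
    tilt: dict
    geometry: dict
    params: dict
    analysis: dict
    run: dict
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, user: dict | None = None) -> "RunConfig":
        cfg = _merge_strict(_DEFAULT_CONFIG, user or {})
        a = np.atleast_1d(cfg["protocol"]["a_max_g"])
        v = np.atleast_1d(cfg["protocol"]["v_max_mps"])
        if a.size != v.size:
            raise ValidationError("a_max_g and v_max_mps must have the same length")
        trans_axis = cfg["protocol"]["axis"]
        tilt_axis = cfg["tilt"]["axis"]
        if _AXIS_PAIRS.get(trans_axis) != tilt_axis:
            raise ValidationError(
                f"contradictory axis settings: translation axis {trans_axis!r} pairs "
                f"with tilt axis {_AXIS_PAIRS.get(trans_axis)!r}, got {tilt_axis!r}")
        if cfg["protocol"]["kind"] != "translation":
            raise ValidationError("protocol.kind must be 'translation'")
        return cls(protocol=cfg["protocol"], tilt=cfg["tilt"],
                   geometry=cfg["geometry"], params=cfg["params"],
                   analysis=cfg["analysis"], run=cfg["run"], raw=cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(user)

    @classmethod
    def for_plane(cls, plane: str, overrides: dict | None = None) -> "RunConfig":
        """Convenience: 'roll' (utricular) or 'pitch' (saccular) protocols."""
        user = dict(overrides or {})
        if plane == "pitch":
            user.setdefault("protocol", {})["axis"] = "naso_occipital"
            user.setdefault("tilt", {})["axis"] = "pitch"
        elif plane != "roll":
            raise ValidationError("plane must be 'roll' or 'pitch'")
        return cls.from_dict(user)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def camera_geometry(self) -> CameraGeometry:
        return CameraGeometry(**self.geometry)

    def reflex_params(self):
        from .synthetic import ReflexParams
        return ReflexParams(**self.params)
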