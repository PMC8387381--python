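"""Stimulus-response extraction and the otolith-ocular-reflex index.

The reflex under study is *torsion-like eye movement*: disconjugate (roll
plane) or conjugate (pitch plane) vertical eye movement that compensates
for the angle between the body axis and the gravito-inertial acceleration
(GIA), whether that angle is produced by actual tilt or by translational
acceleration.  The analysis chain is:

1. per-eye **shift angles** — baseline-relative vertical-component
   excursions per acceleration direction (translation) or plateau-mean
   deviations (stepped tilt);
2. **binocular combination** — (L - R)/2 for roll-plane contexts,
   (L + R)/2 for pitch-plane contexts;
3. a **response table** of combined shift vs signed body-axis-to-GIA
   angle, averaged across animals with 95% confidence intervals;
4. an OLS line per table; the **index** is the mean of the absolute
   slopes of the translation-derived and tilt-derived lines,

    index = (amplitude of vertical eye-movement component)
            / (angle between body axis and GIA),

   a single dimensionless gain that assesses the utricle (roll-plane
   protocols) or the saccule (pitch-plane protocols) without knowing
   whether the stimulus was tilt or translation.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, ProtocolMismatchError, ValidationError
from .eye_rotation import EyeSeries
from .kinematics import (GiaSeries, MotionProfile, TiltSchedule,
                         TranslationAxis, TiltAxis, stimulus_gia_angle)


class Context(str, enum.Enum):
    lateral_translation = "lateral_translation"
    roll_tilt = "roll_tilt"
    naso_translation = "naso_translation"
    pitch_tilt = "pitch_tilt"

    @property
    def plane(self) -> str:
        return "roll" if self in (Context.lateral_translation, Context.roll_tilt) else "pitch"


def context_for_stimulus(stimulus) -> Context:
    """Analysis context implied by a stimulus description."""
    if isinstance(stimulus, MotionProfile):
        return (Context.lateral_translation if stimulus.axis is TranslationAxis.interaural
                else Context.naso_translation)
    if isinstance(stimulus, TiltSchedule):
        return Context.roll_tilt if stimulus.axis is TiltAxis.roll else Context.pitch_tilt
    raise ValidationError(f"unsupported stimulus type: {type(stimulus).__name__}")


@dataclass
class ShiftMeasurement:
    """One stimulus level: signed GIA angle and per-eye/combined shifts."""

    stimulus_deg: float
    shift_left_deg: float
    shift_right_deg: float
    combined_deg: float
    context: Context


class PlateauSkipWarning(UserWarning):
    """A tilt plateau was too short to yield a usable mean."""


def combine_binocular(shift_left_deg: float, shift_right_deg: float,
                      context: Context | str) -> float:
    """Binocular combination of per-eye vertical shift angles.

    (L - R)/2 for roll-plane contexts (lateral translation, roll tilt,
    where the vertical movement is disconjugate) and (L + R)/2 for
    pitch-plane contexts (naso-occipital translation, pitch tilt).
    """
    context = Context(context)
    if context.plane == "roll":
        return (shift_left_deg - shift_right_deg) / 2.0
    return (shift_left_deg + shift_right_deg) / 2.0


# ---------------------------------------------------------------------------
# shift extraction
# ---------------------------------------------------------------------------


def _on_eye_grid(series: EyeSeries, stim_time: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Resample a stimulus-grid signal onto the eye-series time base."""
    if values.shape == series.time.shape and np.allclose(stim_time, series.time):
        return values
    return np.interp(series.time, stim_time, values)


def extract_translation_shifts(
    left: EyeSeries,
    right: EyeSeries,
    profile: MotionProfile,
    component: str = "vertical",
    window_legs: tuple[int, ...] = (3, 4),
    mode: str = "peak_stimulus",
) -> list[ShiftMeasurement]:
    """Per-direction shift angles for a translation run.

    Within the analysis window (``window_legs``, 1-based one-way legs), the
    profile is split into epochs of constant acceleration sign.  The shift
    of each eye for a direction is its baseline-relative deviation of the
    chosen component, averaged over that direction's epochs; the stimulus
    is the signed body-axis-to-GIA angle at the epoch extremum (so e.g. a
    0.9 G setting yields stimulus levels of about +/-41.99 degrees).

    ``mode='peak_stimulus'`` (default) reads each eye at the sample where
    |GIA angle| peaks inside the epoch — the maximum-excursion sample under
    the zero-lag reflex model and unbiased under landmark noise.
    ``mode='peak_response'`` reads the literal maximum |deviation| sample
    of each eye instead.

    Returns one :class:`ShiftMeasurement` per acceleration direction.
    """
    if mode not in ("peak_stimulus", "peak_response"):
        raise ValidationError(f"unknown extraction mode {mode!r}")
    if len(left) != len(right) or not np.allclose(left.time, right.time):
        raise ProtocolMismatchError("left/right eye series are not on a shared time base")
    context = context_for_stimulus(profile)

    stim = stimulus_gia_angle(profile)
    s = _on_eye_grid(left, stim.time, stim.gia_deg)
    accel = _on_eye_grid(left, profile.time, profile.accel_g)
    # leg labels: nearest-sample lookup (exact when grids coincide)
    idx = np.clip(np.searchsorted(profile.time, left.time - 0.5 / profile.rate_hz), 0,
                  len(profile) - 1)
    legs = profile.leg_index[idx]

    comp_l = left.component(component)
    comp_r = right.component(component)

    onset = np.argmax(np.abs(accel) > 1e-9)
    if not np.any(np.abs(accel) > 1e-9):
        raise ProtocolMismatchError("profile contains no motion")
    if onset == 0:
        raise ProtocolMismatchError("no pre-motion samples available for the baseline")
    base_l = float(np.nanmean(comp_l[:onset]))
    base_r = float(np.nanmean(comp_r[:onset]))

    in_window = np.isin(legs, np.asarray(window_legs))
    sgn = np.sign(accel)
    sgn[np.abs(accel) <= 1e-9] = 0.0

    out: list[ShiftMeasurement] = []
    for direction in (1.0, -1.0):
        active = in_window & (sgn == direction)
        if not np.any(active):
            raise ProtocolMismatchError(
                f"no epoch with acceleration sign {direction:+.0f} in legs {window_legs}")
        # split into contiguous epochs
        edges = np.nonzero(np.diff(active.astype(int)))[0] + 1
        bounds = np.concatenate([[0], edges, [active.size]])
        stims, shifts_l, shifts_r = [], [], []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if not active[a]:
                continue
            seg = slice(a, b)
            ok = left.valid[seg] & right.valid[seg]
            if not np.any(ok):
                continue
            rel = np.nonzero(ok)[0]
            if mode == "peak_stimulus":
                i = rel[np.argmax(np.abs(s[seg][rel]))]
                il = ir = i
            else:
                il = rel[np.nanargmax(np.abs(comp_l[seg][rel] - base_l))]
                ir = rel[np.nanargmax(np.abs(comp_r[seg][rel] - base_r))]
                i = rel[np.argmax(np.abs(s[seg][rel]))]
            stims.append(s[seg][i])
            shifts_l.append(comp_l[seg][il] - base_l)
            shifts_r.append(comp_r[seg][ir] - base_r)
        if not stims:
            raise ProtocolMismatchError(
                f"all epochs with acceleration sign {direction:+.0f} were invalid")
        sl, sr = float(np.mean(shifts_l)), float(np.mean(shifts_r))
        out.append(ShiftMeasurement(
            stimulus_deg=float(np.mean(stims)),
            shift_left_deg=sl, shift_right_deg=sr,
            combined_deg=combine_binocular(sl, sr, context),
            context=context))
    return out


def extract_tilt_shifts(
    left: EyeSeries,
    right: EyeSeries,
    schedule: TiltSchedule,
    component: str = "vertical",
    central_frac: float = 0.6,
    min_plateau_s: float = 1.0,
) -> list[ShiftMeasurement]:
    """Per-plateau shift angles for a stepped-tilt run.

    The shift at each plateau is the mean of the chosen component over the
    central ``central_frac`` of the plateau, minus the same mean on the
    first 0-degree plateau (the zero reference).  Plateaus shorter than
    ``min_plateau_s`` are skipped with a :class:`PlateauSkipWarning`.
    Returns one :class:`ShiftMeasurement` per usable plateau (repeated
    visits to the same angle give repeated rows).
    """
    if len(left) != len(right) or not np.allclose(left.time, right.time):
        raise ProtocolMismatchError("left/right eye series are not on a shared time base")
    if len(left) != len(schedule) or not np.allclose(left.time, schedule.time):
        raise ProtocolMismatchError("eye series and tilt schedule are not time-aligned")
    context = context_for_stimulus(schedule)
    comp_l = left.component(component)
    comp_r = right.component(component)

    def plateau_mean(pid: int):
        idx = np.nonzero(schedule.plateau_index == pid)[0]
        if idx.size / schedule.rate_hz < min_plateau_s:
            warnings.warn(
                f"plateau {pid} ({schedule.plateau_levels[pid]:g} deg) shorter than "
                f"{min_plateau_s:g} s; skipped", PlateauSkipWarning)
            return None
        lo = int(np.floor(idx.size * (1.0 - central_frac) / 2.0))
        hi = idx.size - lo
        sel = idx[lo:hi]
        return (float(np.nanmean(comp_l[sel])), float(np.nanmean(comp_r[sel])))

    zero_pids = [p for p, lev in enumerate(schedule.plateau_levels) if lev == 0.0]
    if not zero_pids:
        raise ProtocolMismatchError("schedule has no 0-degree reference plateau")
    ref = plateau_mean(zero_pids[0])
    if ref is None:
        raise ProtocolMismatchError("0-degree reference plateau is too short to use")

    out: list[ShiftMeasurement] = []
    for pid, level in enumerate(schedule.plateau_levels):
        m = plateau_mean(pid) if pid != zero_pids[0] else ref
        if m is None:
            continue
        sl, sr = m[0] - ref[0], m[1] - ref[1]
        out.append(ShiftMeasurement(
            stimulus_deg=float(level), shift_left_deg=sl, shift_right_deg=sr,
            combined_deg=combine_binocular(sl, sr, context), context=context))
    return out


# ---------------------------------------------------------------------------
# response tables and the index fit
# ---------------------------------------------------------------------------


@dataclass
class ResponseTable:
    """Population stimulus-response table for one context.

    ``data`` columns: context, stimulus_deg, mean_shift_deg, ci95_deg
    (half-width of the t-based 95% confidence interval across animals; NaN
    when only one animal contributed), n.
    """

    data: pd.DataFrame
    context: Context
    n_animals: int

    @property
    def stimulus_deg(self) -> np.ndarray:
        return self.data["stimulus_deg"].to_numpy()

    @property
    def mean_shift_deg(self) -> np.ndarray:
        return self.data["mean_shift_deg"].to_numpy()


def build_response_table(per_animal: dict, context: Context | str | None = None,
                         ) -> ResponseTable:
    """Average shift measurements across animals per stimulus level.

    Parameters
    ----------
    per_animal : dict
        animal id -> sequence of :class:`ShiftMeasurement`.  Repeated
        measurements of one level within an animal are averaged first, so
        each animal contributes one value per level.
    """
    if not per_animal:
        raise ValidationError("no animals provided")
    rows = []
    for animal, ms in per_animal.items():
        for m in ms:
            if context is None:
                context = m.context
            elif Context(context) is not Context(m.context):
                raise ValidationError("mixed contexts in one response table")
            rows.append((animal, round(float(m.stimulus_deg), 6), float(m.combined_deg)))
    context = Context(context)
    df = pd.DataFrame(rows, columns=["animal", "stimulus_deg", "shift_deg"])
    if df["stimulus_deg"].nunique() < 2:
        raise ValidationError("a response table needs at least 2 distinct stimulus levels")
    per = df.groupby(["stimulus_deg", "animal"])["shift_deg"].mean().reset_index()

    from scipy import stats

    def level_stats(g: pd.Series):
        n = g.size
        mean = g.mean()
        if n < 2:
            ci = np.nan
        else:
            ci = stats.t.ppf(0.975, n - 1) * g.std(ddof=1) / np.sqrt(n)
        return pd.Series({"mean_shift_deg": mean, "ci95_deg": ci, "n": n})

    out = (per.groupby("stimulus_deg")["shift_deg"].apply(level_stats).unstack()
           .reset_index())
    out["n"] = out["n"].astype(int)
    out.insert(0, "context", context.value)
    return ResponseTable(out, context, n_animals=df["animal"].nunique())


@dataclass
class IndexEstimate:
    """Fitted otolith-ocular-reflex index.

    ``slope_translation`` / ``slope_tilt`` are absolute OLS slopes
    (dimensionless, deg/deg); the raw signed slopes are retained alongside.
    ``index`` is exactly the unweighted mean of the two absolute slopes.
    """

    slope_translation: float
    slope_tilt: float
    index: float
    slope_translation_signed: float
    slope_tilt_signed: float
    intercept_translation_deg: float
    intercept_tilt_deg: float
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "slope_translation": self.slope_translation,
            "slope_tilt": self.slope_tilt,
            "slope_translation_signed": self.slope_translation_signed,
            "slope_tilt_signed": self.slope_tilt_signed,
            "intercept_translation_deg": self.intercept_translation_deg,
            "intercept_tilt_deg": self.intercept_tilt_deg,
            "diagnostics": self.diagnostics,
        }


def fit_line(table: ResponseTable, through_origin: bool = False) -> dict:
    """OLS line through the level-averaged points of one table."""
    x = table.stimulus_deg
    y = table.mean_shift_deg
    if np.unique(np.round(x, 9)).size < 2:
        raise FitError("cannot fit a line to a single stimulus level")
    X = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[-1])
    intercept = 0.0 if through_origin else float(res.params[0])
    resid = y - res.predict(X)
    return {
        "slope": slope,
        "intercept_deg": intercept,
        "r_squared": float(res.rsquared),
        "residual_sd_deg": float(np.sqrt(np.mean(resid**2))),
        "n_points": int(x.size),
    }


def fit_index(table_translation: ResponseTable, table_tilt: ResponseTable,
              through_origin: bool = False) -> IndexEstimate:
    """Fit both stimulus-response lines and average their inclinations.

    The index is the unweighted mean of the absolute slopes of the
    translation-derived and tilt-derived lines; both raw slopes, the
    intercepts (expected near zero) and fit diagnostics are retained.
    """
    ft = fit_line(table_translation, through_origin)
    fg = fit_line(table_tilt, through_origin)
    s_t, s_g = abs(ft["slope"]), abs(fg["slope"])
    return IndexEstimate(
        slope_translation=s_t,
        slope_tilt=s_g,
        index=(s_t + s_g) / 2.0,
        slope_translation_signed=ft["slope"],
        slope_tilt_signed=fg["slope"],
        intercept_translation_deg=ft["intercept_deg"],
        intercept_tilt_deg=fg["intercept_deg"],
        diagnostics={"translation": ft, "tilt": fg,
                     "through_origin": through_origin},
    )
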