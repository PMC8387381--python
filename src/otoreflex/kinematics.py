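"""Stimulus kinematics for otolith stimulation protocols.

Two stimulus families drive the otolith organs with the same
gravito-inertial ambiguity:

* **Linear sled translation** — the head is carried along a straight rail
  (interaural or naso-occipital axis) through repeated one-way legs with a
  stationary dwell at each end.  Each leg accelerates, optionally cruises at
  peak velocity, and decelerates; the acceleration pulse has raised-cosine
  edges so the profile is smooth (twice differentiable in position).
* **Stepped static tilt** — the body is rotated about the roll or pitch
  axis in fixed angular increments, held at each plateau for several
  seconds, with slow constant-rate ramps in between so the semicircular
  canals contribute as little as possible.

The gravito-inertial acceleration (GIA) is the vector sum of gravity and
the inertial reaction to linear acceleration.  During translation on a
level rail the angle between the body's gravity-aligned axis and the GIA is

    gamma(t) = -atan(a(t) / g)            [degrees]

with ``a`` the signed translational acceleration in units of g; during
static tilt the GIA is gravity itself and the angle equals the tilt angle.
That shared angle is the stimulus variable of the reflex index fitted in
:mod:`otoreflex.reflex`.

Sign conventions (used package-wide):

* translation axis: rightward positive (interaural), forward positive
  (naso-occipital);
* tilt: leftward roll positive, backward pitch positive;
* angles in degrees on every public surface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterizationError, ValidationError

#: standard gravity, m/s^2
G_MPS2 = 9.80665


class TranslationAxis(str, enum.Enum):
    interaural = "interaural"
    naso_occipital = "naso_occipital"


class TiltAxis(str, enum.Enum):
    roll = "roll"
    pitch = "pitch"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MotionProfile:
    """Sled motion along one translation axis on a uniform time grid.

    Attributes
    ----------
    time : ndarray
        Seconds, uniform grid.
    position_mm : ndarray
        Signed position along the motion axis, millimetres.
    velocity_mps : ndarray
        Signed velocity, m/s.
    accel_g : ndarray
        Signed acceleration as a fraction of standard gravity (G units).
    axis : TranslationAxis
    leg_index : ndarray of int
        1-based one-way leg number per sample; -1 during dwells.
    meta : dict
        Generator parameters (a_max_g, v_max_mps, one_way_mm, ...).
    """

    time: np.ndarray
    position_mm: np.ndarray
    velocity_mps: np.ndarray
    accel_g: np.ndarray
    axis: TranslationAxis
    leg_index: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


@dataclass
class TiltSchedule:
    """Stepped whole-body tilt about the roll or pitch axis.

    ``plateau_index`` labels each sample with the 0-based plateau it belongs
    to (-1 during ramps); ``plateau_levels`` maps plateau index to the held
    angle in degrees.
    """

    time: np.ndarray
    tilt_deg: np.ndarray
    axis: TiltAxis
    plateau_index: np.ndarray
    plateau_levels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


@dataclass
class GiaSeries:
    """Signed angle between the body axis and the gravito-inertial vector."""

    time: np.ndarray
    gia_deg: np.ndarray

    def __len__(self) -> int:
        return self.time.size


# ---------------------------------------------------------------------------
# sled leg construction
# ---------------------------------------------------------------------------
#
# One leg is symmetric: an acceleration phase (raised-cosine rise of length
# t_r to the peak A, hold of length t_h at A, raised-cosine fall of length
# t_r back to zero, by which time velocity has reached V), an optional cruise
# of length t_c at V, then the mirrored deceleration phase.  Degrees of
# freedom t_r and t_c are solved so that peak acceleration, peak velocity and
# leg displacement simultaneously match the requested values.


def _accel_phase_distance(t_r: float, A: float, V: float) -> float:
    """Displacement covered while velocity rises from 0 to V.

    Closed form for the cosine-edged trapezoidal pulse with rise/fall time
    ``t_r`` and hold time ``t_h = V/A - t_r`` at peak acceleration ``A``.
    """
    t_h = V / A - t_r
    v1 = A * t_r / 2.0  # velocity after the rise
    d_rise = A * t_r**2 * (0.25 - 1.0 / np.pi**2)
    d_hold = v1 * t_h + A * t_h**2 / 2.0
    v2 = v1 + A * t_h
    d_fall = v2 * t_r + A * t_r**2 * (0.25 + 1.0 / np.pi**2)
    return d_rise + d_hold + d_fall


def _solve_leg(L: float, A: float, V: float) -> tuple[float, float, float]:
    """Solve (t_r, t_h, t_c) for a leg of length L (m), peak accel A (m/s^2),
    peak velocity V (m/s)."""
    d_min = V * V / A  # square-pulse limit: shortest leg that reaches V
    if d_min > L * (1.0 + 1e-9):
        raise ParameterizationError(
            f"infeasible sled leg: reaching {V} m/s and stopping again at "
            f"<= {A / G_MPS2:.3g} G requires {d_min * 1e3:.0f} mm "
            f"> one-way length {L * 1e3:.0f} mm"
        )
    d_full = _accel_phase_distance(V / A, A, V)  # full raised cosine, = V^2/A... at t_h=0
    if 2.0 * d_full <= L:
        # pure raised-cosine pulse fits; make up the distance with a cruise
        t_r = V / A
        t_c = (L - 2.0 * d_full) / V
    else:
        # shorten the cosine edges (grow the flat hold) until the leg fits
        t_r = brentq(lambda tr: 2.0 * _accel_phase_distance(tr, A, V) - L, 1e-12, V / A)
        t_c = 0.0
    t_h = V / A - t_r
    return t_r, t_h, t_c


def _eval_leg(t: np.ndarray, t_r: float, t_h: float, t_c: float, A: float):
    """Closed-form (x, v, a) in SI units at times ``t`` within one leg.

    The second half of the leg mirrors the first: x(t) = L - x(T - t),
    v(t) = v(T - t), a(t) = -a(T - t).
    """
    V = A * (t_r + t_h)
    t_a = 2.0 * t_r + t_h  # end of acceleration phase
    T = 2.0 * t_a + t_c
    d_acc = _accel_phase_distance(t_r, A, V)
    L = 2.0 * d_acc + V * t_c

    t = np.asarray(t, dtype=float)
    mirrored = t > T / 2.0
    u = np.where(mirrored, T - t, t)

    x = np.empty_like(u)
    v = np.empty_like(u)
    a = np.empty_like(u)

    v1 = A * t_r / 2.0
    d_rise = A * t_r**2 * (0.25 - 1.0 / np.pi**2)
    v2 = v1 + A * t_h
    d_hold = d_rise + v1 * t_h + A * t_h**2 / 2.0

    m = u <= t_r
    if np.any(m):
        tt = u[m]
        a[m] = A * (1.0 - np.cos(np.pi * tt / t_r)) / 2.0
        v[m] = A / 2.0 * (tt - (t_r / np.pi) * np.sin(np.pi * tt / t_r))
        x[m] = A / 2.0 * (tt**2 / 2.0 + (t_r / np.pi) ** 2 * (np.cos(np.pi * tt / t_r) - 1.0))
    m = (u > t_r) & (u <= t_r + t_h)
    if np.any(m):
        tt = u[m] - t_r
        a[m] = A
        v[m] = v1 + A * tt
        x[m] = d_rise + v1 * tt + A * tt**2 / 2.0
    m = (u > t_r + t_h) & (u <= t_a)
    if np.any(m):
        tt = u[m] - t_r - t_h
        a[m] = A * (1.0 + np.cos(np.pi * tt / t_r)) / 2.0
        v[m] = v2 + A / 2.0 * (tt + (t_r / np.pi) * np.sin(np.pi * tt / t_r))
        x[m] = d_hold + v2 * tt + A / 2.0 * (
            tt**2 / 2.0 + (t_r / np.pi) ** 2 * (1.0 - np.cos(np.pi * tt / t_r))
        )
    m = u > t_a
    if np.any(m):
        tt = u[m] - t_a
        a[m] = 0.0
        v[m] = V
        x[m] = d_acc + V * tt

    x = np.where(mirrored, L - x, x)
    a = np.where(mirrored, -a, a)
    return x, v, a


def make_translation_profile(
    one_way_mm: float = 1800.0,
    a_max_g: float = 0.9,
    v_max_mps: float = 3.25,
    dwell_s: float = 0.3,
    n_round_trips: int = 5,
    rate_hz: float = 240.0,
    axis: TranslationAxis | str = TranslationAxis.interaural,
    lead_in_s: float = 1.0,
    first_direction: int = -1,
) -> MotionProfile:
    """Generate a reciprocating sled profile.

    The sled rests for ``lead_in_s`` (baseline for the eye-position
    reference), then performs ``2 * n_round_trips`` one-way legs of
    ``one_way_mm`` each, with a ``dwell_s`` stationary dwell after every leg.
    Within a leg the acceleration pulse has raised-cosine edges and a flat
    hold at ``a_max_g``; rise time and cruise time are solved so that peak
    |acceleration|, peak |velocity| and the leg displacement match the
    requested values exactly (in closed form; the sampled series agrees to
    well under 1%).

    Parameters
    ----------
    first_direction : int
        Sign of the first leg (-1: the sled starts at the rightmost /
        frontmost end and moves in the negative direction first, as in the
        experimental protocol).

    Raises
    ------
    ParameterizationError
        If no leg of the requested length can reach ``v_max_mps`` while
        keeping |acceleration| <= ``a_max_g``.
    """
    axis = TranslationAxis(axis)
    if min(one_way_mm, a_max_g, v_max_mps, rate_hz) <= 0:
        raise ParameterizationError("one_way_mm, a_max_g, v_max_mps, rate_hz must be positive")
    if dwell_s < 0 or lead_in_s < 0 or n_round_trips < 1:
        raise ParameterizationError("dwell_s/lead_in_s must be >= 0 and n_round_trips >= 1")
    if first_direction not in (-1, 1):
        raise ParameterizationError("first_direction must be +1 or -1")

    L = one_way_mm / 1000.0
    A = a_max_g * G_MPS2
    V = float(v_max_mps)
    t_r, t_h, t_c = _solve_leg(L, A, V)
    T_leg = 2.0 * (2.0 * t_r + t_h) + t_c

    n_legs = 2 * n_round_trips
    T_total = lead_in_s + n_legs * (T_leg + dwell_s)
    n = int(round(T_total * rate_hz)) + 1
    t = np.arange(n) / rate_hz

    pos = np.zeros(n)
    vel = np.zeros(n)
    acc = np.zeros(n)
    leg_idx = np.full(n, -1, dtype=int)

    for k in range(n_legs):
        start = lead_in_s + k * (T_leg + dwell_s)
        direction = first_direction * (1 if k % 2 == 0 else -1)
        x0_mm = 0.0 if k % 2 == 0 else first_direction * one_way_mm
        in_leg = (t >= start) & (t < start + T_leg)
        x, v, a = _eval_leg(t[in_leg] - start, t_r, t_h, t_c, A)
        pos[in_leg] = x0_mm + direction * x * 1000.0
        vel[in_leg] = direction * v
        acc[in_leg] = direction * a / G_MPS2
        leg_idx[in_leg] = k + 1
        # dwell after the leg: parked at the far end
        in_dwell = (t >= start + T_leg) & (t < start + T_leg + dwell_s + 0.5 / rate_hz)
        pos[in_dwell] = x0_mm + direction * one_way_mm

    meta = dict(
        one_way_mm=one_way_mm, a_max_g=a_max_g, v_max_mps=v_max_mps, dwell_s=dwell_s,
        n_round_trips=n_round_trips, rate_hz=rate_hz, lead_in_s=lead_in_s,
        first_direction=first_direction, t_rise_s=t_r, t_hold_s=t_h, t_cruise_s=t_c,
    )
    return MotionProfile(t, pos, vel, acc, axis, leg_idx, meta)


# ---------------------------------------------------------------------------
# stepped tilt
# ---------------------------------------------------------------------------


def make_tilt_schedule(
    max_deg: float = 70.0,
    step_deg: float = 10.0,
    dwell_s: float = 5.0,
    ramp_rate_dps: float = 4.0,
    direction_order: str = "positive_first",
    axis: TiltAxis | str = TiltAxis.roll,
    rate_hz: float = 60.0,
) -> TiltSchedule:
    """Generate a stepped tilt schedule.

    Plateaus run 0 -> +max -> 0 -> -max -> 0 in ``step_deg`` increments
    (``direction_order='negative_first'`` swaps the halves), each held for
    ``dwell_s``, joined by constant-rate ramps at ``ramp_rate_dps``.
    Positive angles are leftward tilt (roll) or backward tilt (pitch).
    """
    axis = TiltAxis(axis)
    if step_deg <= 0 or ramp_rate_dps <= 0 or dwell_s <= 0 or rate_hz <= 0:
        raise ParameterizationError("step_deg, ramp_rate_dps, dwell_s, rate_hz must be positive")
    if max_deg < 0:
        raise ParameterizationError("max_deg must be >= 0")
    n_steps = max_deg / step_deg
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ParameterizationError(
            f"step_deg={step_deg} does not divide max_deg={max_deg}"
        )
    n_steps = int(round(n_steps))
    if direction_order not in ("positive_first", "negative_first"):
        raise ValidationError("direction_order must be 'positive_first' or 'negative_first'")

    sign0 = 1.0 if direction_order == "positive_first" else -1.0
    up = [sign0 * step_deg * i for i in range(n_steps + 1)]            # 0 .. +max
    levels = up + up[-2::-1]                                           # back to 0
    down = [-sign0 * step_deg * i for i in range(1, n_steps + 1)]      # -step .. -max
    levels += down + down[-2::-1] + ([0.0] if n_steps else [])
    if n_steps == 0:
        levels = [0.0]

    # build segment list: (duration, level_from, level_to, plateau_id or -1)
    segments: list[tuple[float, float, float, int]] = []
    for i, lev in enumerate(levels):
        if i > 0:
            prev = levels[i - 1]
            segments.append((abs(lev - prev) / ramp_rate_dps, prev, lev, -1))
        segments.append((dwell_s, lev, lev, i))

    T_total = sum(s[0] for s in segments)
    n = int(round(T_total * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    tilt = np.empty(n)
    plateau = np.full(n, -1, dtype=int)

    t0 = 0.0
    for dur, lev0, lev1, pid in segments:
        m = (t >= t0 - 1e-12) & (t < t0 + dur - 1e-12)
        if lev0 == lev1:
            tilt[m] = lev0
        else:
            tilt[m] = lev0 + (lev1 - lev0) * (t[m] - t0) / dur
        if pid >= 0:
            plateau[m] = pid
        t0 += dur
    # last sample
    tilt[-1] = levels[-1]
    plateau[-1] = len(levels) - 1

    meta = dict(max_deg=max_deg, step_deg=step_deg, dwell_s=dwell_s,
                ramp_rate_dps=ramp_rate_dps, direction_order=direction_order,
                rate_hz=rate_hz)
    return TiltSchedule(t, tilt, axis, plateau, np.asarray(levels, dtype=float), meta)


# ---------------------------------------------------------------------------
# GIA angle
# ---------------------------------------------------------------------------


def gia_from_acceleration(accel_g: np.ndarray) -> np.ndarray:
    """GIA tilt angle in degrees from signed acceleration in G units.

    gamma = (-1) * atan(a / g); with ``a`` already a fraction of g this is
    -atan(a) elementwise, in degrees.  Odd in ``a`` and bounded by +/-90 deg.
    """
    return -np.degrees(np.arctan(np.asarray(accel_g, dtype=float)))


def gia_tilt_angle(profile: MotionProfile) -> GiaSeries:
    """GIA tilt-angle series for a translation profile."""
    return GiaSeries(profile.time, gia_from_acceleration(profile.accel_g))


def gia_angle_for_tilt(schedule: TiltSchedule) -> GiaSeries:
    """During tilt the GIA is gravity itself, so the body-axis-to-GIA angle
    is the tilt angle sample-for-sample."""
    return GiaSeries(schedule.time, np.array(schedule.tilt_deg, dtype=float, copy=True))


def stimulus_gia_angle(stimulus) -> GiaSeries:
    """Body-axis-to-GIA angle in the *plotted* sign convention.

    Translation: rightward (interaural) / forward (naso-occipital)
    acceleration on the positive side, i.e. -gamma = +atan(a).  Tilt:
    the signed tilt angle itself (leftward roll / backward pitch positive).
    This is the abscissa convention of the population stimulus-response
    graphs and the stimulus variable of the reflex index.
    """
    if isinstance(stimulus, MotionProfile):
        g = gia_tilt_angle(stimulus)
        return GiaSeries(g.time, -g.gia_deg)
    if isinstance(stimulus, TiltSchedule):
        return gia_angle_for_tilt(stimulus)
    raise ValidationError(f"unsupported stimulus type: {type(stimulus).__name__}")


# ---------------------------------------------------------------------------
# marker tracking
# ---------------------------------------------------------------------------


def marker_to_position(marker_x: np.ndarray, mm_per_unit: float,
                       reference_x: float = 0.0) -> np.ndarray:
    """Sled position (mm) from the camera coordinate of the sled marker."""
    if mm_per_unit <= 0:
        raise ValidationError("mm_per_unit must be positive")
    return (np.asarray(marker_x, dtype=float) - reference_x) * mm_per_unit


def markers_to_tilt_deg(marker_a: np.ndarray, marker_b: np.ndarray) -> np.ndarray:
    """Tilt angle (deg) of the line connecting two board-marker centres.

    ``marker_a``/``marker_b`` are (..., 2) camera coordinates.  Raises
    ValidationError if the two markers coincide at any frame.
    """
    a = np.atleast_2d(np.asarray(marker_a, dtype=float))
    b = np.atleast_2d(np.asarray(marker_b, dtype=float))
    d = b - a
    degenerate = np.hypot(d[..., 0], d[..., 1]) < 1e-12
    if np.any(degenerate):
        idx = int(np.argmax(degenerate))
        raise ValidationError(f"coincident tilt markers at frame {idx}: angle undefined")
    ang = np.degrees(np.arctan2(d[..., 1], d[..., 0]))
    return ang if np.asarray(marker_a).ndim > 1 else float(ang[0])
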