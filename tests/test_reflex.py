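"""Shift extraction, binocular combination, tables and the index fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otoreflex import (Context, EyeSeries, FitError, ReflexParams,
                       ValidationError, build_response_table,
                       combine_binocular, components_to_rotvec,
                       extract_tilt_shifts, extract_translation_shifts,
                       fit_index, make_tilt_schedule, make_translation_profile,
                       simulate_reflex, stimulus_gia_angle)
from otoreflex.reflex import ShiftMeasurement, fit_line


def _series_pair(time, vert_left, vert_right, rate_note=None):
    def mk(eye, vert):
        comps = np.zeros((time.size, 3))
        comps[:, 1] = vert
        return EyeSeries(time=time, eye=eye, rotvec=components_to_rotvec(comps),
                         components_deg=comps)
    return mk("left", vert_left), mk("right", vert_right)


# ---------------------------------------------------------------------------
# binocular combination
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("l,r,context,expected", [
    (10.0, -10.0, "roll_tilt", 10.0),
    (10.0, 10.0, "pitch_tilt", 10.0),
    (7.2, -6.8, "lateral_translation", 7.0),
    (3.0, 5.0, "naso_translation", 4.0),
])
def test_combine_binocular_formulas(l, r, context, expected):
    assert combine_binocular(l, r, context) == pytest.approx(expected)


def test_combine_binocular_rejects_unknown_context():
    with pytest.raises(ValueError):
        combine_binocular(1.0, 2.0, "sideways")


@given(l=st.floats(-30, 30), r=st.floats(-30, 30), a=st.floats(-3, 3))
@settings(max_examples=50, deadline=None)
def test_combine_binocular_linearity_and_eye_swap(l, r, a):
    for ctx in Context:
        base = combine_binocular(l, r, ctx)
        assert combine_binocular(a * l, a * r, ctx) == pytest.approx(a * base, abs=1e-9)
    # swapping eyes negates the lateral combination, preserves the naso one
    assert combine_binocular(r, l, "roll_tilt") == pytest.approx(
        -combine_binocular(l, r, "roll_tilt"))
    assert combine_binocular(r, l, "pitch_tilt") == pytest.approx(
        combine_binocular(l, r, "pitch_tilt"))


# ---------------------------------------------------------------------------
# translation shift extraction
# ---------------------------------------------------------------------------


def test_translation_shifts_from_proportional_response(small_translation):
    """vertical = 0.3 * gamma(t) yields per-direction shifts of -/+12.60 deg
    at stimulus levels +/-atan(0.9)."""
    p = small_translation
    gamma = -stimulus_gia_angle(p).gia_deg  # the printed-formula GIA angle
    left, right = _series_pair(p.time, 0.3 * gamma, -0.3 * gamma)
    ms = extract_translation_shifts(left, right, p)
    by_stim = {round(m.stimulus_deg, 2): m for m in ms}
    assert set(by_stim) == {41.99, -41.99}
    assert by_stim[41.99].shift_left_deg == pytest.approx(-12.596, abs=5e-3)
    assert by_stim[-41.99].shift_left_deg == pytest.approx(12.596, abs=5e-3)
    # combined (L-R)/2 mirrors the left eye here
    assert by_stim[41.99].combined_deg == pytest.approx(-12.596, abs=5e-3)


def test_translation_shifts_zero_series_and_baseline_invariance(small_translation):
    p = small_translation
    z = np.zeros(p.time.size)
    left, right = _series_pair(p.time, z, z)
    ms = extract_translation_shifts(left, right, p)
    assert all(m.shift_left_deg == 0 and m.shift_right_deg == 0 for m in ms)
    # constant offset applied from the very start is removed by the baseline
    left2, right2 = _series_pair(p.time, z + 3.0, z - 1.5)
    ms2 = extract_translation_shifts(left2, right2, p)
    for m in ms2:
        assert m.shift_left_deg == pytest.approx(0.0, abs=1e-12)
        assert m.shift_right_deg == pytest.approx(0.0, abs=1e-12)


def test_translation_window_without_requested_legs_raises(small_translation):
    from otoreflex import ProtocolMismatchError
    p = small_translation
    left, right = _series_pair(p.time, np.zeros(p.time.size), np.zeros(p.time.size))
    with pytest.raises(ProtocolMismatchError):
        extract_translation_shifts(left, right, p, window_legs=(9, 10))


# ---------------------------------------------------------------------------
# tilt shift extraction
# ---------------------------------------------------------------------------


def test_tilt_shifts_stepwise_series(small_tilt):
    s = small_tilt
    left, right = _series_pair(s.time, 0.3 * s.tilt_deg, -0.3 * s.tilt_deg)
    ms = extract_tilt_shifts(left, right, s)
    assert len(ms) == len(s.plateau_levels)
    m30 = [m for m in ms if m.stimulus_deg == 30.0][0]
    assert m30.shift_left_deg == pytest.approx(9.0, abs=1e-9)
    assert m30.shift_right_deg == pytest.approx(-9.0, abs=1e-9)
    assert m30.combined_deg == pytest.approx(9.0, abs=1e-9)
    # zero-gain series -> all shifts zero
    lz, rz = _series_pair(s.time, np.zeros(s.time.size), np.zeros(s.time.size))
    assert all(m.combined_deg == 0 for m in extract_tilt_shifts(lz, rz, s))


def test_tilt_central_window_equals_full_mean_when_stepwise(small_tilt):
    s = small_tilt
    left, right = _series_pair(s.time, 0.2 * s.tilt_deg, -0.2 * s.tilt_deg)
    narrow = extract_tilt_shifts(left, right, s, central_frac=0.6)
    full = extract_tilt_shifts(left, right, s, central_frac=1.0)
    for a, b in zip(narrow, full):
        assert a.combined_deg == pytest.approx(b.combined_deg, abs=1e-12)


def test_short_plateaus_warn_and_skip():
    from otoreflex.reflex import PlateauSkipWarning
    s = make_tilt_schedule(max_deg=10, step_deg=10, dwell_s=0.5, rate_hz=30.0)
    left, right = _series_pair(s.time, 0.3 * s.tilt_deg, -0.3 * s.tilt_deg)
    from otoreflex import ProtocolMismatchError
    with pytest.warns(PlateauSkipWarning):
        with pytest.raises(ProtocolMismatchError):  # even the reference is short
            extract_tilt_shifts(left, right, s, min_plateau_s=1.0)


# ---------------------------------------------------------------------------
# response tables
# ---------------------------------------------------------------------------


def _measurements(levels, gain, context="roll_tilt", jitter=0.0, rng=None):
    out = []
    for lev in levels:
        y = gain * lev + (rng.normal(0, jitter) if jitter else 0.0)
        out.append(ShiftMeasurement(lev, y, -y, combine_binocular(y, -y, context),
                                    Context(context)))
    return out


def test_identical_animals_give_zero_ci():
    levels = [-20.0, 0.0, 20.0]
    per_animal = {i: _measurements(levels, 0.3) for i in range(10)}
    table = build_response_table(per_animal)
    assert table.n_animals == 10
    assert np.allclose(table.data["ci95_deg"], 0.0)
    assert np.allclose(table.data["n"], 10)


def test_single_animal_ci_is_absent_not_fabricated():
    table = build_response_table({0: _measurements([-10.0, 10.0], 0.3)})
    assert np.isnan(table.data["ci95_deg"]).all()


def test_translation_abscissa_is_gia_angle_of_each_setting(geometry,
                                                           noise_free_params):
    """The five sled settings land at +/-atan(a_max) on the stimulus axis."""
    settings_av = [(0.2, 1.69), (0.3, 2.24), (0.7, 3.06), (0.9, 3.25), (1.3, 3.25)]
    ms = []
    for a, v in settings_av:
        p = make_translation_profile(a_max_g=a, v_max_mps=v, n_round_trips=2,
                                     rate_hz=60.0)
        gamma = -stimulus_gia_angle(p).gia_deg
        left, right = _series_pair(p.time, 0.3 * gamma, -0.3 * gamma)
        ms.extend(extract_translation_shifts(left, right, p))
    table = build_response_table({0: ms})
    got = sorted(np.round(table.stimulus_deg, 2))
    expected = sorted([s * x for x in (11.31, 16.70, 34.99, 41.99, 52.43)
                       for s in (+1, -1)])
    assert got == pytest.approx(expected, abs=0.01)


def test_table_requires_two_stimulus_levels():
    with pytest.raises(ValidationError):
        build_response_table({0: _measurements([10.0], 0.3)})


# ---------------------------------------------------------------------------
# index fit
# ---------------------------------------------------------------------------


def test_fit_index_recovers_exact_line():
    levels = np.arange(-70.0, 80.0, 10.0)
    t1 = build_response_table({0: _measurements(levels, 0.297)})
    t2 = build_response_table({0: _measurements(levels, 0.297)})
    est = fit_index(t1, t2)
    assert est.index == pytest.approx(0.297, abs=1e-12)
    assert est.intercept_translation_deg == pytest.approx(0.0, abs=1e-9)
    assert est.diagnostics["tilt"]["r_squared"] == pytest.approx(1.0)


def test_index_is_mean_of_two_slopes():
    levels = np.arange(-40.0, 50.0, 10.0)
    ta = build_response_table({0: _measurements(levels, 0.30)})
    tb = build_response_table({0: _measurements(levels, 0.10)})
    est = fit_index(ta, tb)
    assert est.index == pytest.approx(0.20, abs=1e-12)
    assert est.index == (est.slope_translation + est.slope_tilt) / 2.0


def test_fit_rejects_single_level_table():
    levels = [-10.0, 10.0]
    table = build_response_table({0: _measurements(levels, 0.3)})
    table.data = table.data.iloc[:1]
    with pytest.raises(FitError):
        fit_line(table)


# ---------------------------------------------------------------------------
# component-level end-to-end (no camera in the loop)
# ---------------------------------------------------------------------------


def test_noise_free_gain_recovery_is_exact(small_translation, small_tilt,
                                           noise_free_params):
    """Simulated series analysed with the same chain recover the generating
    gain to 1e-6 with zero intercepts, and the translation- and tilt-derived
    lines coincide (the overlay property)."""
    left_t, right_t = simulate_reflex(small_translation, noise_free_params)
    left_g, right_g = simulate_reflex(small_tilt, noise_free_params)
    ms_t = extract_translation_shifts(left_t, right_t, small_translation)
    ms_g = extract_tilt_shifts(left_g, right_g, small_tilt)
    table_t = build_response_table({0: ms_t})
    table_g = build_response_table({0: ms_g})
    est = fit_index(table_t, table_g)
    g = noise_free_params.gain_roll_vertical
    assert est.slope_translation == pytest.approx(g, abs=1e-6)
    assert est.slope_tilt == pytest.approx(g, abs=1e-6)
    assert est.intercept_translation_deg == pytest.approx(0.0, abs=1e-6)
    assert est.intercept_tilt_deg == pytest.approx(0.0, abs=1e-6)
    assert abs(est.slope_translation_signed - est.slope_tilt_signed) < 1e-6
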