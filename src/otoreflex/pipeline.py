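"""End-to-end pipeline: simulate -> reconstruct -> extract -> fit.

`run_pipeline` composes every stage for one plane (roll/utricular or
pitch/saccular): it simulates a cohort on the translation protocol (the
five sled settings) and the stepped-tilt protocol, reconstructs 3D eye
series from the landmark tracks, extracts shift angles, builds the two
population response tables, fits the index, and writes the report files.
"""

from __future__ import annotations

import json
import logging
import sys
import time as _time
from pathlib import Path

import numpy as np

from . import __version__
from .errors import PipelineError
from .eye_rotation import CameraGeometry, series_reconstruct
from .io import RunConfig, write_landmark_csv, write_motion_profile_csv, \
    write_response_table_csv, write_tilt_schedule_csv
from .kinematics import MotionProfile, TiltSchedule, make_tilt_schedule, \
    make_translation_profile
from .reflex import (Context, IndexEstimate, build_response_table,
                     extract_tilt_shifts, extract_translation_shifts, fit_index)
from .synthetic import SimulatedExperiment, simulate_cohort

log = logging.getLogger("otoreflex")


def setting_tag(stimulus) -> str:
    """Short file tag for a stimulus: '0p9g' for a 0.9 G profile, 'tilt'."""
    if isinstance(stimulus, MotionProfile):
        return f"{stimulus.meta['a_max_g']:g}".replace(".", "p") + "g"
    return "tilt"


def _setup_logging(level: str = "INFO", json_lines: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _J(logging.Formatter):
            def format(self, record):
                return json.dumps({"level": record.levelname, "msg": record.getMessage()})
        handler.setFormatter(_J())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def build_protocols(config: RunConfig) -> list[MotionProfile | TiltSchedule]:
    """Stimuli implied by a config: one profile per sled setting + the tilt."""
    p = config.protocol
    a_list = np.atleast_1d(p["a_max_g"]).tolist()
    v_list = np.atleast_1d(p["v_max_mps"]).tolist()
    protocols: list[MotionProfile | TiltSchedule] = [
        make_translation_profile(
            one_way_mm=p["one_way_mm"], a_max_g=a, v_max_mps=v,
            dwell_s=p["dwell_s"], n_round_trips=p["n_round_trips"],
            rate_hz=p["rate_hz"], axis=p["axis"], lead_in_s=p["lead_in_s"])
        for a, v in zip(a_list, v_list)
    ]
    t = config.tilt
    protocols.append(make_tilt_schedule(
        max_deg=t["max_deg"], step_deg=t["step_deg"], dwell_s=t["dwell_s"],
        ramp_rate_dps=t["ramp_rate_dps"], axis=t["axis"], rate_hz=t["rate_hz"],
        direction_order=t["direction_order"]))
    return protocols


def analyze_experiment(exp: SimulatedExperiment, geometry: CameraGeometry,
                       analysis: dict):
    """Reconstruct one experiment's tracks and extract its shift angles."""
    left = series_reconstruct(exp.track_left, geometry,
                              reference_window_s=analysis["reference_window_s"])
    right = series_reconstruct(exp.track_right, geometry,
                               reference_window_s=analysis["reference_window_s"])
    if isinstance(exp.stimulus, MotionProfile):
        return extract_translation_shifts(
            left, right, exp.stimulus, component=analysis["component"],
            window_legs=tuple(analysis["window_legs"]), mode=analysis["mode"])
    return extract_tilt_shifts(
        left, right, exp.stimulus, component=analysis["component"],
        central_frac=analysis["central_frac"])


def recover_index(experiments: list[SimulatedExperiment],
                  geometry: CameraGeometry, analysis: dict):
    """Full analysis of a simulated cohort.

    Returns (translation table, tilt table, :class:`IndexEstimate`).
    """
    per_animal_t: dict[int, list] = {}
    per_animal_g: dict[int, list] = {}
    for exp in experiments:
        ms = analyze_experiment(exp, geometry, analysis)
        bucket = (per_animal_t if isinstance(exp.stimulus, MotionProfile)
                  else per_animal_g)
        bucket.setdefault(exp.animal_id, []).extend(ms)
    if not per_animal_t or not per_animal_g:
        raise PipelineError("analyze", "cohort must include both a translation "
                            "and a tilt protocol")
    table_t = build_response_table(per_animal_t)
    table_g = build_response_table(per_animal_g)
    estimate = fit_index(table_t, table_g, through_origin=analysis["through_origin"])
    return table_t, table_g, estimate


def _plot_tables(table_t, table_g, estimate: IndexEstimate, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for table, color, label, slope, icpt in (
            (table_t, "tab:red", "translation", estimate.slope_translation_signed,
             estimate.intercept_translation_deg),
            (table_g, "tab:blue", "tilt", estimate.slope_tilt_signed,
             estimate.intercept_tilt_deg)):
        x = table.stimulus_deg
        ax.errorbar(x, table.mean_shift_deg, yerr=table.data["ci95_deg"],
                    fmt="s" if color == "tab:red" else "D", ms=4, color=color,
                    label=f"{label} (slope {slope:.3f})")
        xx = np.array([x.min(), x.max()])
        ax.plot(xx, icpt + slope * xx, color=color, lw=1)
    ax.set_xlabel("body-axis-to-GIA angle (deg)")
    ax.set_ylabel("combined vertical shift (deg)")
    ax.set_title(f"otolith-ocular-reflex index = {estimate.index:.3f}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, out_dir, write_tracks: bool = False) -> dict:
    """Execute the full pipeline and write report files into ``out_dir``.

    Writes stimulus CSVs, response-table CSVs, an ``index.json`` report
    (slopes, intercepts, diagnostics, config hash, stage timings) and a
    stimulus-response plot.  Any stage error is re-raised as
    :class:`PipelineError` carrying the stage name; ``index.json`` is only
    written on success, so a partial output directory is identifiable by
    its absence.
    """
    _setup_logging(config.run.get("log_level", "INFO"))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    chash = config.config_hash()

    def stage(name, fn, *args, **kw):
        t0 = _time.perf_counter()
        try:
            result = fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(name, str(exc)) from exc
        timings[name] = round(_time.perf_counter() - t0, 3)
        log.info("stage %-12s %6.2f s", name, timings[name])
        return result

    protocols = stage("kinematics", build_protocols, config)
    geometry = config.camera_geometry()
    experiments = stage("simulate", simulate_cohort, protocols,
                        config.reflex_params(), config.run["n_animals"],
                        config.run["seed"], geometry)
    table_t, table_g, estimate = stage(
        "analyze", recover_index, experiments, geometry, config.analysis)

    for proto in protocols:
        if isinstance(proto, MotionProfile):
            write_motion_profile_csv(proto, out / f"profile_{setting_tag(proto)}.csv")
        else:
            write_tilt_schedule_csv(proto, out / "tilt_schedule.csv")
    if write_tracks:
        for exp in experiments:
            write_landmark_csv(
                [exp.track_left, exp.track_right],
                out / f"animal{exp.animal_id:02d}_{setting_tag(exp.stimulus)}_landmarks.csv")
    write_response_table_csv(table_t, out / "response_translation.csv")
    write_response_table_csv(table_g, out / "response_tilt.csv")
    if config.run.get("plot", True):
        stage("plot", _plot_tables, table_t, table_g, estimate, out / "response_lines.png")

    report = {
        "otoreflex_version": __version__,
        "config_hash": chash,
        "n_animals": config.run["n_animals"],
        "seed": config.run["seed"],
        "contexts": [table_t.context.value, table_g.context.value],
        "estimate": estimate.to_dict(),
        "config": config.raw,
    }
    # wall-clock stage timings are logged and written separately so that
    # index.json stays byte-identical across reruns of the same config+seed
    (out / "timings.json").write_text(json.dumps(timings, indent=2) + "\n")
    (out / "index.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                               default=float) + "\n")
    log.info("index = %.4f (translation %.4f, tilt %.4f)", estimate.index,
             estimate.slope_translation, estimate.slope_tilt)
    return report
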