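# Methods

## Overview

`otoreflex` implements a desk-scale model of a binocular video-oculography
experiment on the otolith-ocular reflex, together with the analysis that
turns such recordings into a single reflex index. The pipeline has four
stages, each usable on its own: stimulus kinematics, 3D eye-position
reconstruction from landmarks, stimulus-response extraction and fitting,
and a forward (synthetic) model that generates landmark recordings with
known ground-truth gains.

## Stimulus kinematics

**Sled translation.** A run consists of a stationary lead-in (default 1 s,
used as the eye-position reference window), then `2 × n_round_trips`
one-way legs of `one_way_mm` (default 1800 mm) separated by stationary
dwells (default 0.3 s). Within a leg the acceleration pulse is a
raised-cosine-edged trapezoid: cosine rise of duration `t_r` to the peak
`a_max`, flat hold of duration `t_h`, cosine fall back to zero (velocity
then at `v_max`), an optional cruise `t_c`, and the mirrored deceleration.
The constraint `a_max·(t_r + t_h) = v_max` leaves two free parameters
(`t_r`, `t_c`), solved in closed form / by `brentq` so that peak
acceleration, peak velocity **and** leg displacement are met
simultaneously. A pure raised-cosine pulse (the smoothest member of the
family) is used whenever it fits within the leg; for settings where the
full cosine would overrun the leg (e.g. 0.9 G at 3.25 m/s over 1800 mm,
which would need 2.39 m) the cosine edges shorten and the flat hold grows,
approaching a square pulse in the limit. Legs shorter than `v²/a` are
rejected as infeasible with the violated constraint named. Position,
velocity and acceleration are evaluated piecewise in closed form, so the
sampled series is exact at every grid point; all five protocol sled
settings (1.3 G/3.25, 0.9 G/3.25, 0.7 G/3.06, 0.3 G/2.24, 0.2 G/1.69 m/s)
reproduce both extrema and the 1800 mm displacement to machine precision.

**Stepped tilt.** Plateaus run 0 → +max → 0 → −max → 0 in `step_deg`
increments (default 10°, max 70°), each held `dwell_s` (default 5 s),
joined by constant-rate ramps at `ramp_rate_dps`. The experimental
protocol specifies both a ramp rate band (3–5°/s) and a ramp duration
(2–3 s), which cannot hold simultaneously for a 10° step; we expose the rate (default
4°/s, the band midpoint) and derive the duration.

**GIA angle.** During translation the body-axis-to-GIA angle is
γ(t) = −atan(a(t)/g); during tilt it is the tilt angle itself. The
*plotted* stimulus variable used on the response-table abscissa follows the
population-graph conventions: rightward/forward acceleration on the
positive side (i.e. −γ), leftward-roll / backward-pitch tilt positive.
With these conventions the translation- and tilt-derived lines of a shared
reflex gain coincide, which is the property the index rests on.

## Eye-position representation and reconstruction

Eye position is a rotation vector **r** = **n** tan(θ/2) relative to the
stationary reference pose, with axis-angle readout θ = 2 atan(|r|) and
components θ·r_i/|r| (X torsional, Y vertical, Z horizontal, degrees).

The reconstruction model is a rigid spherical eye of known pixel radius
under orthographic projection (appropriate for a small eye at large camera
distance): the pupil centre and the iris freckle are points on the sphere;
an image point (u, v) relative to the projected eye centre lifts to the
unit direction (√(1−u²−v²), u, v) on the front hemisphere. Each frame's
orientation is solved from the (pupil, freckle) direction pair by the
orthonormal-triad (TRIAD) attitude method — the pupil direction fixes two
degrees of freedom, the freckle bearing fixes torsion — and the reported
rotation is relative to the reference frame. Because two unit vectors with
a fixed included angle determine a rotation uniquely, this is the same
rotation any order of horizontal/vertical/torsional factorisation would
produce, and it makes reconstruction the *exact* inverse of the forward
projection: the round-trip error on 1000 random poses up to 60° total
angle is ~1e−13 degrees.

Choices and limits:

* **Reference pose** = mean landmark geometry over the first 0.5 s
  (half-open window), which every protocol keeps stationary. The freckle
  offset is calibrated from the reference frame itself, so no separate
  freckle calibration is needed.
* **Camera-axis correction**: applied after reconstruction, rotating the
  analysed vector about Z by +angle (left eye) / −angle (right eye).
  Dark-condition protocols use 0° (camera directly beside the eye).
* **Failure handling**: frames whose landmarks leave the eye disc, whose
  freckle collapses onto the pupil centre (torsion unobservable), or whose
  total rotation exceeds 90° are flagged invalid and set to NaN, never
  silently dropped; single-frame API calls raise typed errors instead.
* Pupil-size changes, perspective effects, corneal refraction and eyelid
  occlusion are outside the model.

## Shift extraction, combination and the index

**Translation.** The analysis window defaults to one-way legs 3–4
(configurable). Within the window, epochs of constant acceleration sign
are identified; the per-eye shift for a direction is the baseline-relative
deviation of the vertical component (baseline = pre-motion mean), averaged
across that direction's epochs, and the stimulus is the GIA angle at the
epoch extremum (±atan(a_max/g)). By default the deviation is read at the
sample where |GIA angle| peaks inside the epoch: under the zero-lag
response model this *is* the maximum excursion, and unlike a literal
per-sample max it is unbiased under landmark noise (a literal max inflates
every level by roughly the upper tail of the smoothed noise, which
propagates into the fitted slope). A `peak_response` mode implementing the
literal maximum |deviation| is available for data with response lag.

**Tilt.** The shift at each plateau is the mean of the component over the
central 60% of the plateau (robust to ramp edges) minus the same mean on
the first 0° plateau; plateaus shorter than 1 s are skipped with a
recorded warning. For exactly stepwise series the central-60% mean equals
the full-plateau mean.

**Combination and tables.** Per-eye shifts combine as (L−R)/2 (roll-plane
contexts) or (L+R)/2 (pitch-plane contexts). Response tables average the
combined shift across animals per signed stimulus level, with t-based 95%
confidence intervals (reported absent, not fabricated, for a single
animal).

**Fit.** Ordinary least squares with a free intercept on the
level-averaged points (through-origin as an option); the intercept is
retained as a diagnostic and is ≈ 0 on synthetic data. The index is the
unweighted mean of the **absolute** slopes of the translation and tilt
lines; raw signed slopes, R² and residual SDs are reported alongside.

## Synthetic-data generator

The generator encodes the study conditions: five sled settings at 240 Hz
with 1800 mm legs and 0.3 s dwells; stepped tilt 0–70° in 10° steps with
5 s dwells at 60 Hz; cohorts of 10 animals.

Each component of each eye is (sign) × gain × s(t), where s(t) is the
plotted GIA angle — the response depends on instantaneous acceleration,
never on sled position. Sign patterns per context are chosen so the
binocular combinations return exactly gain × s on noise-free data:
vertical (+1, −1) in roll-plane contexts and (+1, +1) in pitch-plane
contexts; pitch-plane torsional and horizontal are disconjugate (+1, −1);
the small roll-plane horizontal component is conjugate. Default gains:
0.297 (roll vertical), 0.173 (pitch vertical), 0.17 (pitch torsional),
0.02 (horizontal; the magnitude of the "slight" conjugate rotation is not
quantified anywhere, so this is an explicit placeholder).

Noise model: Gaussian pixel noise on each landmark coordinate (default
0.5 px on a 120 px eye radius ≈ 0.24° angular noise per frame) plus
optional additive Gaussian angle noise. Between-animal variability is
emulated by jittering each animal's vertical gains (SD 0.02 by default),
which produces realistic error bars in the population tables; cohort noise
streams are spawned per animal from a master `SeedSequence`, so identical
configuration + seed regenerates bit-identical CSVs. Optional features,
off by default: a first-order response lag, and sawtooth quick-phase
resetting confined to the horizontal component (no quick-phase detection
is implemented downstream — the vertical-component index is argued to be
robust to them, and the generator lets users test exactly that).

What the generator does **not** emulate: real pupil/freckle detection
error statistics (blinks, glints, segmentation bias), eye-position-
dependent noise, canal-ocular contributions during ramps, habituation or
drift. Passing recovery tests therefore demonstrates correctness of the
geometry and estimation chain under the stated model, not performance on
raw video.

## Problem sizes and numerics

The bundled cohort runs use 10 animals × (5 translation profiles at 240 Hz
+ 1 tilt protocol at 60 Hz) ≈ 2.6 M reconstructed frames in a few seconds;
test fixtures use shortened protocols (2 round trips, 20–60 Hz, 30° tilt
ceilings) chosen to keep the suite fast while preserving every structural
feature (legs 3–4 exist, both stimulus signs occur, plateaus exceed the
1 s minimum). Tolerances: sled extrema/displacement are met to closed-form
precision and tested at the 1% contract; reconstruction round-trip is
tested at 0.1° (observed ~1e−13); noise-free end-to-end gain recovery is
tested at 1e−3 (observed ~1e−9); Monte-Carlo unbiasedness is tested at two
standard errors over 200 replicates. CSV serialisation uses 9 significant
digits, which round-trips all quantities used here.

## Known limitations

* The reconstruction assumes the orthographic spherical-eye model used by
  the forward simulator; with real video the projection model, eye-centre
  estimate and radius calibration would dominate the error budget.
* The index inherits the assumptions of OLS on level means; heteroscedastic
  animal effects are summarised only through the per-level CIs.
* Quick phases are neither detected nor removed; analyses of data with
  substantial fast phases in the *vertical* component would bias the
  translation extractor.
* Only accelerations perpendicular to gravity are modelled (no free-fall /
  gravity-magnitude manipulation).
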