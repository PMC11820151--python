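# Methods

`broilertrack` analyzes data from combined UWB + accelerometer wearables
on broiler chickens and ships a synthetic pen simulator that provides
ground truth for every stage. This note records the models, the
parameters that matter, and the choices made where the design was open.

## TDOA localization model

A tag transmits one packet; `n` synchronized anchors at known positions
`a_i` timestamp its arrival. Converting time differences to meters gives
range differences relative to a reference anchor (index 0 by
convention):

```
delta_i = ||p - a_i|| - ||p - a_0||,   i = 1..n-1
```

with three-dimensional ranges evaluated at a fixed tag height (0.10 m;
anchor height 0.30 m enters only through these ranges — reported
positions are 2-D). `solve_tdoa` minimizes the residuals
`(||p - a_i|| - ||p - a_0||) - delta_i` by nonlinear least squares
(`scipy.optimize.least_squares`, analytic Jacobian, anchor-centroid
start, step/gradient tolerances ~1e-9 m / 1e-12, ≤100 iterations;
non-convergence is flagged, never silent).

**Noise model.** Timing noise is independent per anchor with sd `sigma`
(in meters), so the delta vector has covariance `sigma^2 (I + 11')` —
every delta shares the reference anchor's noise. Residuals are whitened
by `(I + 11')^(-1/2)` before minimization, which (a) makes the estimate
independent of the reference-anchor choice and (b) makes the linearized
position covariance the generalized-least-squares form

```
cov(p) = sigma^2 (J' (I + 11')^{-1} J)^{-1},    GDOP = sqrt(tr cov) / sigma
```

computed by `gdop_covariance`. This model yields exactly the geometry
seen in static-tag data: near-isotropic noise at the center of a
symmetric layout and larger, x/y-correlated ellipses near anchors, where
the hyperbolic constraints become nearly parallel. A simpler
`sigma^2 (J'J)^{-1}` (independent delta noise) was rejected because it
predicts substantial x/y correlation even at the center of a square
layout, contradicting both symmetry and observed behavior. Note that
|corr(x, y)| peaks roughly 0.3–0.4 m from a corner anchor and dips in
the last decimeters before it, where the linearization degrades; the
monotone-anisotropy test therefore starts 0.3 m out.

**Confidence ellipses.** `characterize_static_noise` uses the sample
mean and covariance (n−1 denominator, ≥30 fixes required); 95% ellipse
semi-axes are `sqrt(5.991 * eigenvalue)` from the chi-square(2)
quantile. Coverage of the fitted ellipse is ~95% of fixes by
construction for Gaussian noise.

## Pen simulator

**Behavior** is a four-state continuous-time Markov chain over REST,
FORAGE, DRINK, WALK. REST alternates with activity bouts; on leaving
REST the bird picks FORAGE/DRINK/WALK with probabilities (0.4, 0.2, 0.4).
Dwell times are exponential with phase-dependent means. Activity bouts
average 60 s in light and 30 s in dark (calibration knobs — no published
bout statistics exist for this setup). The REST dwell mean per phase is
set analytically so that each phase realizes its target REST fraction:
the dark phase rests at 0.92 and the light phase at whatever value makes
the 24 h mixture hit the overall target (default 0.76, matching the
reported ~76% inactive time; the light schedule is 16L:8D with dark
02:00–06:00 and 20:00–24:00). The chain is time-inhomogeneous across
phase boundaries: the remaining dwell is re-drawn at each boundary with
the new phase's rate, which is exact for exponential dwells. Over 7
simulated days the realized REST fraction lands within ±0.03 of target.

**Trajectory** (1 s internal step): REST is stationary; FORAGE/DRINK
birds walk at 0.25 m/s to the nearest matching attractor and jitter
within its radius; WALK is a correlated random walk (heading noise sd
0.6 rad/step) reflected at the walls. Displacement per step never
exceeds `max_speed * step` (default 0.5 m/s) and positions stay in-pen.

**IMU** (20 Hz): sample = mount-rotated gravity unit vector + white
per-axis sensor noise (sd 0.01 g) + per-axis burst noise (sd 0.2 g) only
while not resting. Mounts are arbitrary rotations (orientation differs
per bird); magnitude is mount-invariant, and noiseless resting samples
have magnitude exactly 1 g. Burst sd 0.2 g ≫ the 0.05 g threshold keeps
active/inactive separable, which is the regime the threshold rule
assumes.

**UWB fixes** sample the trajectory once per started 32 s period.
`direct` mode draws noise from the local GDOP covariance rescaled so the
per-axis sd at the pen center is 0.08 m (consistent with reading the
"<20 cm" accuracy claim as a 95th-percentile-style bound); `solver` mode
generates per-anchor timing noise (sd 0.05 m by default), forms deltas
and runs the real solver. One RNG stream per (seed, tag, stage) means
adding tags or stages never perturbs existing draws.

**Static-noise experiment**: 80 motionless tags on a deterministic grid
across four 9 m × 4 m pens with six anchors each (corners + long-wall
midpoints), 24 h at 1/16 Hz = 5400 fixes per tag.

What the simulator does *not* emulate: multipath/NLOS outliers and
heavy-tailed UWB errors, 3-D motion (wing flaps, jumps), sensor drift
and calibration offsets beyond a constant mount rotation, social
behavior, and growth over weeks. Passing tests therefore demonstrate
the correctness of the analysis chain under the stated statistical
structure, not robustness to every artifact of farm data.

## Activity detection

Magnitude `m = sqrt(ax^2 + ay^2 + az^2)` per sample; a sample is active
iff `|m - baseline|` strictly exceeds the threshold (default 0.05 g; a
deviation exactly at the threshold is inactive — tie handling is
unspecified in the source material, strictness chosen). Baseline is the
tag's whole-trace mean magnitude by default (absorbs constant
calibration offset); a fixed 1 g baseline is available. A 1 s window is
active iff ≥1 sample in it is active; windows are non-overlapping,
aligned to the trace start, partial trailing window dropped. Interval
summaries (default 4 h) report active windows / total windows; the
overall fraction is the duration-weighted mean (= pooled window count).
The threshold sweep is the survival function of |deviation|, hence
monotone non-increasing.

## Spatial metrics

Occupancy histograms use 5 cm bins (axis unit of the source heatmaps;
bin size itself unstated) smoothed with a Gaussian of σ = 3 *cells*
(units unstated in the source; cells chosen), `mode="reflect"` because
reflective boundaries conserve total mass exactly.

Distance walked sums Euclidean steps between consecutive fixes. Fix
pairs with Δt > 2 nominal periods are dropouts and contribute nothing;
a max-speed filter exists but is off by default (speed filtering belongs
to other systems' pipelines). Two opposing biases are quantified by
`distance_bias_experiment`: undersampling a tortuous path underestimates
(ratio < 1 at 32 s), while position noise inflates — for a static tag
with per-axis sd σ the expected inflation is `n·σ·sqrt(pi)` over n
steps (each step is the norm of a 2-D Gaussian difference).

## Fusion and duty cycling

IMU samples are pre-aggregated to 1 s means per channel (x, y, z,
magnitude); windows of 16/60/300/600 s then take the mean or std of the
1-s means, paired with the UWB distance traveled in the same window
(windows anchored at the first common timestamp, non-overlapping, only
full windows kept). Pearson r per configuration, computed on raw
features. On coupled synthetic data the (std, ≥300 s) configurations
dominate every 16 s configuration — short windows mostly contain at most
one fix pair, so their distance feature is badly quantized.

The motion trigger sums per-second magnitude stds over 30 min windows; a
window truly contains movement iff its UWB distance ≥ 5 m. The
low/high split threshold is exposed as a parameter (sweep mode returns
the full ROC-style table). **Separability caveat:** at the default
position noise (0.08 m), noise inflation alone contributes ~8 m per
resting half hour, so every window exceeds the 5 m truth threshold and
no negative class exists. The fusion/trigger experiments therefore run
at 0.02 m position noise, where resting half hours accumulate ~2 m; this
is the separable regime in which a threshold with sensitivity ≥0.95 and
few false negatives exists. `duty_cycle_savings` takes a trigger mask of
arbitrary granularity; a perfect 1 s trigger on a 76%-rest schedule
suppresses ~76% of transmissions.

Uplink bandwidth is `rate × axes × bits / 8` bytes/s per animal
(20 Hz × 3 × 8 bit = 60 B/s).

## Retention reporting

Durations are `detach_day − attach_day` in days of age; per-method
summaries report n, mean, min, max, range and the *sample* sd (n−1 —
validated by the {19, 20} → 0.71 check; a population sd would print
0.50). Censored applications (welfare removals, still-attached at trial
end) are included by default, matching how the trial's table was built;
`exclude_censored` is available. The packaged fixture reproduces every
fully determined row; tissue-glue and superglue durations are not
recoverable from the printed summaries, so those rows carry a
documented consistent synthetic choice flagged "illustrative" by
`fixture_provenance()`.

## Numerical and reproducibility choices

- All randomness flows through `numpy` Generators keyed by
  (seed, tag id, stage); identical configs give byte-identical outputs.
- Timestamps are Unix seconds (float); the simulator's t=0 corresponds
  to a configurable clock hour (default midnight).
- Degenerate inputs: colinear anchors raise a geometry error; singular
  GDOP reports infinity; zero-variance features report r = NaN with a
  note; empty intervals report 0 with a gap flag; traces shorter than
  one window/period raise or warn as documented.
- Problem sizes: behavior calibration and activity recovery use 7
  simulated days; fusion/trigger use one day; the static experiment
  uses its full 80 tags × 24 h; solver exactness uses a 5 cm grid with
  a 1 mm exhaustive oracle at spot-check points.

## Known limitations

- GDOP-shaped Gaussian noise understates the border degradation of real
  UWB installations (no NLOS/multipath), so border-vs-center contrasts
  are ordinal, not calibrated to field magnitudes.
- The behavior chain has no diurnal structure beyond the light/dark
  REST modulation and no social interaction.
- The trigger analysis treats noisy UWB distance as ground truth for
  "movement", inheriting its noise floor; see the separability caveat.
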