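# Methods

## Breathing-motion model

Each channel (target X/Y/Z and chest surrogate S) follows
`A · sin^(2n)(θ(t) − φ·π)` where a single accumulated phase θ advances by
π per breath. Driving all channels from one phase keeps phase-shifted
channels continuous across breath boundaries, which matters because
per-breath period and amplitude are stochastic: period ~
Normal(T̄, σ_T) and amplitude factor ~ Normal(1, σ_A), truncated positive
by resampling and smoothed with a moving-average filter. The amplitude
factor is linearly interpolated between breath starts and, by default,
shared across axes (preserving the trajectory shape breath to breath); an
independent-per-axis mode exists.

Defaults, chosen once as typical of regular patient breathing and used
everywhere:

| parameter | default | meaning |
|---|---|---|
| `period_sd` | 0.1·T̄ s | per-breath period variability |
| `amplitude_rel_sd` | 0.1 | per-breath amplitude variability |
| `smoothing_window` | 3 breaths | moving-average width |
| `drift_amplitude` | 1.0 mm (0 to 2.5 allowed) | baseline-drift magnitude |
| `drift_period` | trace duration | one slow raised-cosine half-cycle |
| `sample_interval` | 0.0125 s | LED-camera rate |

Baseline drift is a raised cosine rising from 0 to `drift_amplitude` in
3D magnitude, split equally (per-axis amplitude /√3) over the three
target axes only — the stage drifts, the chest surrogate does not. The
1.0 mm default is the midpoint of the observed 0–2.5 mm range of slow
baseline shifts. Each axis is mean-centred after synthesis (the phantom
is registered to its mean position), which is what makes the tabulated
3D RMS displacement reproducible from amplitudes alone: for n = 2 and no
variability, per-axis RMS = A·sqrt(E[sin⁸] − E[sin⁴]²) = 0.3644·A.

Phase-shift convention: shifts are cycle fractions (π/2 of waveform
argument = 50%); positive shifts delay the channel.

## Delivery timeline and aliasing

kV radiographs are scheduled evenly in time, `kv_per_rotation` per
gantry rotation, first acquisition one spacing after start. The
images-per-respiration ratio T̄/(gantry_period/kv_per_rotation) flags the
aliasing failure mode: near 1.0, every image samples the same breathing
phase. The `aliasing_index` quantifies this as the circular mean
resultant length of the sampled phases (1 = one phase, ~0 = uniform
coverage). Case fixtures with 3 s breathing use 5 images per 12 s
rotation rather than the 4 used elsewhere, since 4 would give a ratio of
exactly 1.0 — the same remedy applied clinically when aliasing is
observed.

## Tracker emulator

The commercial motion model is proprietary; this package implements a
documented simplification and claims nothing about the commercial
algorithm. Each kV fix contributes a noisy 3D localization (isotropic
Gaussian, `kv_noise_sd` = 0.3 mm default; monoscopic-pair reconstruction
is not modelled, preserving only the sampling-rate behaviour under
study). The correlation model is per-axis linear least squares from
surrogate features to target position, refit on a sliding window
(default 10 fixes) at every new fix, evaluated on the LED grid.

Feature choices (`FeatureSpec`):

- `position`, `position_velocity` — the classic affine maps. These
  cannot rotate the 2nd harmonic of a sin⁴ waveform, so hysteretic
  (phase-shifted) channels leave ~2 mm residuals at realistic
  amplitudes.
- `lagged` — surrogate at fixed time lags (delay embedding).
- `phase_lagged` (default) — surrogate at lags of 0.1 breathing cycle,
  with the cycle measured by a phase estimate built from the surrogate's
  own peak times (peak detection seeded by the autocorrelation period).
  Lagging in phase rather than seconds makes the embedding follow
  period drift; 1 + 4 lag features reproduce the two harmonics of an
  n = 2 waveform. With a static or peak-free surrogate the embedding
  falls back to fixed time lags, and a rank-deficient design falls back
  to an intercept-only model with a warning.

The feature count grows with the window: a full 5-feature fit requires
n_fixes ≥ 8 (= features + 3), and `warmup_fixes` defaults to 8, because
barely-overdetermined early fits produced large transient prediction
errors. Velocity estimates (when used) are Savitzky–Golay derivatives
over 5 LED samples. Models whose 3D fit residual RMS exceeds 3 mm are
flagged low-quality in the log rather than pausing the delivery.

With these defaults, the LEDs-on-phantom configuration tracks all 13
packaged subject cases with δ_RMS ≈ 0.3–1.1 mm and δ_95 ≈ 0.4–2.3 mm at
full treatment lengths — inside the 1.5 mm / 3.0 mm envelope reported
for the physical system, which is the validation target of the test
suite.

## Compensation geometry

The jaws compensate the longitudinal (Y) component of predicted motion
at every gantry angle, so the effective Y residual is the Y prediction
error. In the transverse plane the MLC compensates the component of
motion perpendicular to the beam axis (beam along IEC-Z at gantry 0°);
the component of the prediction error along the beam line is passed
through with weight `along_beam_weight` (default 0: to first order,
motion along the beam does not change the dose). Before the model is
valid the full displacement is uncompensated; in end-to-end case runs
the delivery starts only after a warmup lead of (warmup_fixes + 1) fix
spacings, emulating the clinical pause while the model is built.

## Dose model

No treatment-planning system is involved: the delivery is a parametric
helical sweep chosen to preserve the mechanisms under study (finite
25 mm jaw, couch travel, time-modulated output, rigid phantom motion).
The kernel is separable — an erf-blurred slit of FWHM `jaw_fwhm`
(penumbra sigma 3 mm) in Y times transverse Gaussians (sigma 8 mm) —
and is deposited per time step shifted by the instantaneous effective
displacement, scored in the phantom frame. Output presets: `uniform`
and `checkerboard` (on/off blocks, for interplay studies). Output is
normalized so the static delivery gives dose 1.0 at the target centre.
Grid default: 2 mm spacing over 120×160×120 mm. kV imaging dose is a
uniform per-image term with an exact subtraction inverse (clipped at
zero with a warning).

Consequences verified by the suite: a time-homogeneous delivery blurs
the static dose by exactly the displacement distribution (convolution
identity); time-modulated output synchronized with periodic motion
breaks that identity (interplay); uncompensated motion broadens the
longitudinal penumbra; integral dose is conserved while the beam stays
in-grid.

All dosimetric comparisons are model-level, not plan-level: measured
clinical pass rates depend on plan modulation that this model does not
reproduce. What the tests assert are orderings and identities that are
delivery-model-independent.

## Dose comparison

Gamma uses global normalization (dose criterion as a percent of the
maximum reference dose), a low-dose threshold on reference points, and a
distance search on a 0.2 mm interpolation lattice (configurable; the
search radius defaults to 3× the distance criterion). The implementation
processes offsets in distance-sorted shells with early termination and
is verified against an exhaustive brute-force oracle to 1e-6. Gamma is
directional (reference vs evaluated roles are not symmetric). Multi-case
summary tables compare diode-plane samples (two orthogonal planes,
2.5 mm central / 5 mm peripheral spacing, emulating a commercial QA
phantom's detector layout) by default; full grids are supported.
Median dose difference is taken over reference points above 50% of the
maximum, positive = evaluated hotter. The population comparison is a
two-tailed paired t-test across cases; zero-variance differences raise a
degenerate-case error (reported as degenerate by the study runner).

## Seeds and problem sizes

A master seed is split per case as
`(master·100003 + crc32(case_id)) mod 2³¹`, so per-case streams are
stable across runs and platforms; the tracking loop uses case seed + 1.
Traces for table-reproduction runs use the printed per-case delivery
times; the scenario-ordering study also runs full delivery times but
with a 3 mm grid, 0.5 s dose steps and 0.5 mm gamma interpolation — the
package's desk-scale defaults for multi-case sweeps. Short (50–150 s)
deliveries are not used for scenario ordering because compressing the
sweep makes each voxel's irradiation time comparable to the tracker's
error-correlation time, an artifact absent at realistic durations.

## Known limitations

- The tracker is an emulator: quantitative agreement with the commercial
  system beyond the published error envelope is not claimed.
- No MLC leaf-level sequencing, imaging physics, couch/gantry mechanical
  error, heterogeneity corrections, or absolute dosimetry.
- The synthetic generator produces regular breathing with smooth
  stochastic variation; it does not emulate coughs, breath-holds,
  irregular amplitude drift, or cardiac motion, so passing tests bound
  behaviour only for regular-breathing conditions.
- One motion case's printed RMS (Lung 5) is not reproducible from its
  printed amplitudes under this mean-centred model (4.3 vs 5.6 mm,
  presumably reflecting unprinted drift/variability); it is excluded
  from table-reproduction checks and documented here rather than tuned.
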