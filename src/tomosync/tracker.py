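"""Surrogate-correlation motion-model emulator.

The commercial tracking system periodically localizes the target with kV
radiographs while continuously monitoring an external chest surrogate
(LEDs).  A correlation model maps the surrogate signal to 3D target
position; it is refit every time a new radiograph arrives and evaluated at
the LED rate between radiographs.  The model implemented here is a
documented simplification: a per-axis linear least-squares map from a short
delay embedding of the surrogate signal (current value plus a few lagged
samples, optionally a velocity estimate) to target position.  Lagged
samples let the model represent phase-shifted (hysteretic) target channels
that a pure position-plus-velocity map cannot capture for non-sinusoidal
waveforms.  All quantitative claims are about this emulator, not the
proprietary system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .breathing import MotionTrace, resample_trace
from .delivery import DeliveryConfig, KvFix, kv_schedule

__all__ = [
    "FeatureSpec",
    "CorrelationModel",
    "TrackedTrace",
    "localize_target",
    "fit_correlation_model",
    "predict",
    "run_tracking",
    "compensation_residual",
    "write_tracking_log",
    "read_tracking_log",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Regressor layout of the correlation model.

    mode:
      ``"position"``            -- intercept + surrogate displacement
      ``"position_velocity"``   -- adds a surrogate velocity term
      ``"lagged"``              -- intercept + surrogate at fixed time lags
                                   0, dt, ..., (n_lags-1)*dt
      ``"phase_lagged"``        -- intercept + surrogate at lags measured in
                                   breathing-cycle fraction (default); the
                                   breathing phase is estimated from the
                                   surrogate's own peak times, so the lag
                                   pattern follows period drift

    ``expected_period`` seeds the peak detector; when None it is estimated
    from the surrogate autocorrelation.
    """

    mode: str = "phase_lagged"
    n_lags: int = 4
    lag_spacing: float = 0.5   # s, for mode "lagged"
    lag_phase: float = 0.1     # cycle fraction, for mode "phase_lagged"
    expected_period: Optional[float] = None
    velocity_smooth_samples: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("position", "position_velocity", "lagged",
                             "phase_lagged"):
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if self.mode in ("lagged", "phase_lagged") and self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if not 0 < self.lag_phase < 1:
            raise ValueError("lag_phase must be a cycle fraction in (0, 1)")

    @property
    def n_features(self) -> int:
        if self.mode == "position":
            return 2
        if self.mode == "position_velocity":
            return 3
        return 1 + self.n_lags


def _estimate_period(times: np.ndarray, values: np.ndarray) -> Optional[float]:
    """Dominant breathing period from the surrogate autocorrelation."""
    v = values - values.mean()
    if np.allclose(v, 0):
        return None
    ac = np.correlate(v, v, mode="full")[len(v) - 1:]
    dt = times[1] - times[0]
    peaks, _ = find_peaks(ac, prominence=0.05 * ac[0])
    if len(peaks) == 0:
        return None
    return float(peaks[0] * dt)


class _SurrogateHistory:
    """Surrogate samples on the LED grid with feature evaluation."""

    def __init__(self, times: np.ndarray, values: np.ndarray, spec: FeatureSpec):
        self.times = times
        self.values = values
        self.spec = spec
        self.velocity = None
        self.phase = None
        self._period = spec.expected_period
        if spec.mode == "position_velocity":
            dt = times[1] - times[0]
            win = max(5, spec.velocity_smooth_samples | 1)  # odd, >= 5
            self.velocity = savgol_filter(values, win, polyorder=2,
                                          deriv=1, delta=dt)
        elif spec.mode == "phase_lagged":
            if self._period is None:
                self._period = _estimate_period(times, values)
            self.phase = self._estimate_phase()

    def _estimate_phase(self) -> Optional[np.ndarray]:
        """Cumulative breathing phase (cycles) from surrogate peak times.

        Peaks of the surrogate waveform mark a fixed point of each breath;
        phase advances by one cycle per peak-to-peak interval and is
        linearly interpolated between peaks (linearly extrapolated at the
        edges).  Returns None when the surrogate has no usable peaks
        (e.g. a static channel); the caller then falls back to time lags.
        """
        if self._period is None:
            return None
        dt = self.times[1] - self.times[0]
        rng_v = self.values.max() - self.values.min()
        if rng_v <= 0:
            return None
        peaks, _ = find_peaks(self.values,
                              distance=max(1, int(0.6 * self._period / dt)),
                              prominence=0.2 * rng_v)
        if len(peaks) < 3:
            return None
        pt = self.times[peaks]
        phase = np.interp(self.times, pt, np.arange(len(pt), dtype=float))
        lo = self.times < pt[0]
        hi = self.times > pt[-1]
        phase[lo] = (self.times[lo] - pt[0]) / (pt[1] - pt[0])
        phase[hi] = len(pt) - 1 + (self.times[hi] - pt[-1]) / (pt[-1] - pt[-2])
        return phase

    def features(self, t) -> np.ndarray:
        """(len(t), n_features) design matrix at times t (first column 1)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [np.ones_like(t)]
        if self.spec.mode in ("position", "position_velocity"):
            cols.append(np.interp(t, self.times, self.values))
            if self.spec.mode == "position_velocity":
                cols.append(np.interp(t, self.times, self.velocity))
        elif self.spec.mode == "phase_lagged" and self.phase is not None:
            ph = np.interp(t, self.times, self.phase)
            for k in range(self.spec.n_lags):
                tk = np.interp(ph - k * self.spec.lag_phase, self.phase,
                               self.times)
                cols.append(np.interp(tk, self.times, self.values))
        else:
            # fixed time lags; also the fallback when no phase is available
            spacing = self.spec.lag_spacing
            if self.spec.mode == "phase_lagged":
                spacing = self.spec.lag_phase * (self._period or 4.0)
            for k in range(self.spec.n_lags):
                tk = np.clip(t - k * spacing, self.times[0], self.times[-1])
                cols.append(np.interp(tk, self.times, self.values))
        return np.column_stack(cols)


@dataclass
class CorrelationModel:
    """Per-axis affine map from surrogate features to target position."""

    coef: np.ndarray  # (n_features, 3); row 0 is the intercept
    spec: FeatureSpec
    fit_time: float
    n_fixes_used: int
    fit_residual_rms: float
    intercept_only: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("model coefficients must be finite")

    @property
    def intercept(self) -> np.ndarray:
        return self.coef[0]

    @property
    def slope_position(self) -> np.ndarray:
        """Per-axis coefficient on the instantaneous surrogate value."""
        if self.coef.shape[0] < 2:
            return np.zeros(3)
        return self.coef[1]


def localize_target(trace: MotionTrace, time: float, noise_sd: float,
                    rng: np.random.Generator,
                    gantry_angle: float = 0.0) -> KvFix:
    """Emulate one kV localization: the true position interpolated from the
    trace plus isotropic Gaussian measurement noise."""
    t0, t1 = trace.span()
    if not (t0 - 1e-9 <= time <= t1 + 1e-9):
        raise ValueError(f"localization time {time} outside trace span")
    true = np.array([np.interp(time, trace.times, c)
                     for c in (trace.x, trace.y, trace.z)])
    measured = true + rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else true.copy()
    return KvFix(time=float(time), gantry_angle=float(gantry_angle) % 360.0,
                 measured_position=measured, true_position=true)


def fit_correlation_model(fixes: List[KvFix], surrogate: _SurrogateHistory,
                          min_fixes: int = 2) -> CorrelationModel:
    """Least-squares fit of target position on surrogate features.

    Falls back to an intercept-only model (window mean) with a warning when
    the design matrix is rank deficient, e.g. a constant surrogate or
    phase-aliased sampling.
    """
    if len(fixes) < min_fixes:
        raise ValueError(f"need at least {min_fixes} fixes, got {len(fixes)}")
    t_fix = np.array([f.time for f in fixes])
    Y = np.array([f.measured_position for f in fixes])
    X = surrogate.features(t_fix)
    n_feat = X.shape[1]
    # keep the system comfortably overdetermined: grow the lag count as
    # fixes accumulate, dropping trailing lag columns when the window is
    # still short
    if len(fixes) < n_feat + 3:
        n_feat = max(2, len(fixes) - 3) if len(fixes) >= 5 else max(1, len(fixes) - 1)
        n_feat = min(n_feat, X.shape[1])
        X = X[:, :n_feat]
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    intercept_only = False
    if rank < X.shape[1]:
        warnings.warn("rank-deficient surrogate design; falling back to an "
                      "intercept-only model", stacklevel=2)
        coef = np.zeros((X.shape[1], 3))
        coef[0] = Y.mean(axis=0)
        intercept_only = True
    resid = Y - X @ coef
    full = np.zeros((surrogate.spec.n_features, 3))
    full[:n_feat] = coef
    return CorrelationModel(coef=full, spec=surrogate.spec,
                            fit_time=float(t_fix[-1]), n_fixes_used=len(fixes),
                            fit_residual_rms=float(np.sqrt(np.mean(resid ** 2) * 3)),
                            intercept_only=intercept_only)


def predict(model: CorrelationModel, features: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map: (N, n_features) design -> (N, 3) mm."""
    features = np.atleast_2d(features)
    if features.shape[1] != model.coef.shape[0]:
        raise ValueError("feature dimension does not match the model")
    return features @ model.coef


@dataclass
class TrackedTrace:
    """Tracking log on the LED time grid: predicted vs true positions."""

    times: np.ndarray
    predicted: np.ndarray   # (N, 3) mm
    true: np.ndarray        # (N, 3) mm
    model_valid: np.ndarray  # (N,) bool
    gantry_angle: np.ndarray  # (N,) degrees
    fixes: List[KvFix] = field(default_factory=list)
    low_quality_fraction: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("predicted", "true", "model_valid", "gantry_angle"):
            if len(getattr(self, name)) != n:
                raise ValueError("all tracked series must have equal length")
        if not np.all(np.isfinite(self.predicted[self.model_valid])):
            raise ValueError("predictions must be finite where the model is valid")


def run_tracking(trace: MotionTrace, config: DeliveryConfig,
                 surrogate_source: str = "surrogate",
                 feature_spec: Optional[FeatureSpec] = None,
                 seed: int = 0) -> TrackedTrace:
    """Run the tracking event loop over one delivery.

    The trace is resampled to the LED grid; at each scheduled kV time a
    noisy localization is added to a sliding window of ``model_window``
    fixes and the correlation model is refit; between fixes the latest
    model predicts target position from the surrogate features.  Samples
    before ``warmup_fixes`` localizations are flagged not-yet-modeled.

    surrogate_source: ``"surrogate"`` uses the dedicated chest-surrogate
    channel (LEDs on a separate stage); ``"phantom"`` uses the target Z
    channel (LEDs on the phantom itself).
    """
    if trace.span()[1] < config.treatment_duration - 1e-9:
        raise ValueError("trace is shorter than the treatment duration")
    if feature_spec is None:
        feature_spec = FeatureSpec()
    rng = np.random.default_rng(seed)

    led = resample_trace(trace, config.led_interval)
    keep = led.times <= config.treatment_duration + 1e-9
    t_led = led.times[keep]
    true = np.column_stack([led.x[keep], led.y[keep], led.z[keep]])
    if surrogate_source == "surrogate":
        s_led = led.s[keep]
    elif surrogate_source == "phantom":
        s_led = led.z[keep]
    else:
        raise ValueError(f"unknown surrogate_source {surrogate_source!r}")

    surrogate = _SurrogateHistory(t_led, s_led, feature_spec)
    features = surrogate.features(t_led)
    gantry = (360.0 * t_led / config.gantry_period) % 360.0

    fix_times, fix_angles = kv_schedule(config)
    predicted = np.zeros_like(true)
    valid = np.zeros(len(t_led), dtype=bool)
    fixes: List[KvFix] = []
    n_low_quality = 0
    n_models = 0
    model: Optional[CorrelationModel] = None

    boundaries = np.searchsorted(t_led, fix_times + config.kv_latency, side="left")
    for i, (tf, af) in enumerate(zip(fix_times, fix_angles)):
        fix = localize_target(trace, tf, config.kv_noise_sd, rng, gantry_angle=af)
        fix.surrogate_value = float(np.interp(tf, t_led, s_led))
        fixes.append(fix)
        if len(fixes) >= config.warmup_fixes:
            window = fixes[-config.model_window:]
            model = fit_correlation_model(window, surrogate)
            n_models += 1
            if model.fit_residual_rms > config.fit_residual_threshold:
                n_low_quality += 1
        if model is not None:
            lo = boundaries[i]
            hi = boundaries[i + 1] if i + 1 < len(boundaries) else len(t_led)
            if hi > lo:
                predicted[lo:hi] = predict(model, features[lo:hi])
                valid[lo:hi] = True

    return TrackedTrace(times=t_led, predicted=predicted, true=true,
                        model_valid=valid, gantry_angle=gantry, fixes=fixes,
                        low_quality_fraction=n_low_quality / max(n_models, 1),
                        metadata={"surrogate_source": surrogate_source,
                                  "feature_spec": feature_spec,
                                  "config": config, "seed": seed})


def compensation_residual(tracked: TrackedTrace,
                          along_beam_weight: float = 0.0) -> np.ndarray:
    """Effective uncompensated target displacement per time sample (mm).

    The jaws compensate the longitudinal (Y) component at every angle, so
    the Y residual is the Y prediction error.  In the transverse (X, Z)
    plane the MLC leaves compensate the component perpendicular to the
    beam axis; the prediction-error component along the beam line is
    dosimetrically insensitive to first order and is passed through with
    ``along_beam_weight`` (default 0).  Before the model is valid the full
    true displacement is uncompensated.
    """
    if tracked.gantry_angle is None:
        raise ValueError("tracked trace carries no gantry angles")
    err = tracked.true - tracked.predicted
    theta = np.deg2rad(tracked.gantry_angle)
    # beam axis direction in the transverse plane: gantry 0 -> along Z
    bx, bz = np.sin(theta), np.cos(theta)
    along = err[:, 0] * bx + err[:, 2] * bz
    res = np.empty_like(err)
    res[:, 0] = err[:, 0] - (1.0 - along_beam_weight) * along * bx
    res[:, 2] = err[:, 2] - (1.0 - along_beam_weight) * along * bz
    res[:, 1] = err[:, 1]
    res[~tracked.model_valid] = tracked.true[~tracked.model_valid]
    return res


_LOG_COLUMNS = ["time_s", "pred_x", "pred_y", "pred_z",
                "true_x", "true_y", "true_z", "model_valid", "gantry_deg"]


def write_tracking_log(tracked: TrackedTrace, path) -> None:
    """Write the tracking log CSV (the analog of the machine log file)."""
    df = pd.DataFrame({
        "time_s": tracked.times,
        "pred_x": tracked.predicted[:, 0], "pred_y": tracked.predicted[:, 1],
        "pred_z": tracked.predicted[:, 2],
        "true_x": tracked.true[:, 0], "true_y": tracked.true[:, 1],
        "true_z": tracked.true[:, 2],
        "model_valid": tracked.model_valid.astype(int),
        "gantry_deg": tracked.gantry_angle,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracking_log(path) -> TrackedTrace:
    df = pd.read_csv(path)
    missing = set(_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tracking log missing columns: {sorted(missing)}")
    return TrackedTrace(
        times=df["time_s"].to_numpy(),
        predicted=df[["pred_x", "pred_y", "pred_z"]].to_numpy(),
        true=df[["true_x", "true_y", "true_z"]].to_numpy(),
        model_valid=df["model_valid"].to_numpy().astype(bool),
        gantry_angle=df["gantry_deg"].to_numpy(),
    )
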