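"""Stochastic 3D respiratory motion traces for a motion phantom.

The target (and an external chest surrogate) move according to the Lujan
waveform ``A * sin^(2n)(pi*t/T - phi)``, which spends more time at exhale
than inhale.  Per-breath period and amplitude are drawn from normal
distributions and smoothed with a moving-average filter so that successive
respirations change gradually.  Hysteresis in the sagittal plane is modelled
as a constant phase shift of the vertical (Z) axis relative to Y; an
optional low-frequency cosine models slow baseline drift.  Traces are
registered so each axis has zero temporal mean (the phantom is aligned to
its mean position before delivery).
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "BreathingParameters",
    "MotionTrace",
    "MotionLimitReport",
    "lujan_displacement",
    "phase_fraction_to_radians",
    "generate_breath_sequence",
    "generate_trace",
    "rms_displacement_from_origin",
    "resample_trace",
    "validate_motion_limits",
    "write_trace_csv",
    "read_trace_csv",
]


def phase_fraction_to_radians(p: float) -> float:
    """Convert a phase shift expressed as a cycle fraction to radians.

    The field convention is percent of a breathing cycle: a 50% shift
    (p = 0.5) is pi/2 radians, because one cycle of the ``sin^(2n)``
    waveform spans pi radians of its argument.
    """
    p = float(p)
    if abs(p) > 1:
        raise ValueError(f"phase fraction must satisfy |p| <= 1, got {p}")
    return p * np.pi


def lujan_displacement(t, amplitude: float, period: float, n: int, phase_fraction: float = 0.0):
    """Evaluate ``A * sin^(2n)(pi*t/T - phi)`` at time(s) *t*.

    Parameters
    ----------
    t : float or array
        Time in seconds.
    amplitude : float
        Peak displacement A in mm (waveform range is [0, A]).
    period : float
        Breathing period T in seconds.
    n : int
        Waveform fitting parameter (>= 1); larger n flattens the exhale.
    phase_fraction : float
        Starting phase as a cycle fraction; positive delays the motion.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    if int(n) != n or n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    phi = phase_fraction_to_radians(phase_fraction)
    return amplitude * np.sin(np.pi * np.asarray(t, dtype=float) / period - phi) ** (2 * int(n))


@dataclass
class BreathingParameters:
    """Per-case parameters of the stochastic breathing model.

    Amplitudes are the per-axis Lujan A (mm); ``phase_shift_z`` and
    ``surrogate_phase_shift`` are cycle fractions (0.5 == pi/2); positive
    values delay that channel.  ``amplitude_rel_sd`` and ``period_sd``
    control per-breath variability; ``smoothing_window`` is the width (in
    breaths) of the moving-average filter applied to both sequences.
    """

    mean_amplitude_x: float
    mean_amplitude_y: float
    mean_amplitude_z: float
    mean_period: float = 4.0
    n: int = 2
    phase_shift_z: float = 0.0
    surrogate_phase_shift: float = 0.0
    surrogate_mean_amplitude: float = 5.0
    amplitude_rel_sd: float = 0.1
    period_sd: Optional[float] = None  # defaults to 0.1 * mean_period
    smoothing_window: int = 3
    drift_amplitude: float = 0.0
    drift_period: Optional[float] = None  # defaults to duration (one slow half-cycle)
    duration: float = 300.0
    sample_interval: float = 0.0125
    seed: int = 0
    shared_amplitude_factor: bool = True

    def __post_init__(self) -> None:
        for name in ("mean_amplitude_x", "mean_amplitude_y", "mean_amplitude_z",
                     "surrogate_mean_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_period <= 0:
            raise ValueError("mean_period must be positive")
        if int(self.n) != self.n or not (1 <= self.n <= 3):
            raise ValueError(f"n must be an integer in {{1, 2, 3}}, got {self.n}")
        for name in ("phase_shift_z", "surrogate_phase_shift"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1")
        if self.period_sd is None:
            self.period_sd = 0.1 * self.mean_period
        if self.period_sd < 0 or self.amplitude_rel_sd < 0:
            raise ValueError("variability standard deviations must be >= 0")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1 breath")
        if not (0.0 <= self.drift_amplitude <= 2.5):
            raise ValueError("drift_amplitude must lie in [0, 2.5] mm")
        if self.drift_period is None:
            self.drift_period = self.duration
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.duration < 2 * self.mean_period:
            raise ValueError("duration must cover at least two mean breathing periods")

    def replace(self, **kwargs) -> "BreathingParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass
class MotionTrace:
    """Uniformly sampled target (x, y, z) and surrogate (s) displacements.

    All channels are in mm, registered to zero temporal mean per axis.
    ``cum_phase`` is the accumulated breathing phase in cycles (one breath
    = one cycle), used for phase/aliasing diagnostics.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    s: np.ndarray
    cum_phase: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if n < 2:
            raise ValueError("a trace needs at least two samples")
        for name in ("x", "y", "z", "s"):
            if len(getattr(self, name)) != n:
                raise ValueError("all trace channels must have equal length")
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"channel {name} contains non-finite values")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("times must be a strictly increasing uniform grid")

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def displacement(self) -> np.ndarray:
        """(N, 3) array of target displacement in mm."""
        return np.column_stack([self.x, self.y, self.z])

    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def generate_breath_sequence(params: BreathingParameters,
                             rng: Optional[np.random.Generator] = None,
                             n_breaths: Optional[int] = None):
    """Draw the per-breath (period, amplitude-factor) sequence.

    Periods ~ Normal(mean_period, period_sd) and amplitude factors
    ~ Normal(1, amplitude_rel_sd), both truncated positive by resampling,
    then smoothed with a moving-average filter of ``smoothing_window``
    breaths (nearest-edge handling).

    Returns
    -------
    periods, amplitude_factors : ndarray
        One entry per breath; enough breaths to cover ``params.duration``.
    """
    if params.smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if n_breaths is None:
        # generous margin: shortest plausible breath is mean - 5 sd
        lo = max(params.mean_period - 5 * params.period_sd, 0.2 * params.mean_period)
        n_breaths = int(np.ceil(params.duration / lo)) + params.smoothing_window + 2

    def _truncated_normal(mean, sd, size, lower):
        out = rng.normal(mean, sd, size)
        bad = out <= lower
        while np.any(bad):
            out[bad] = rng.normal(mean, sd, bad.sum())
            bad = out <= lower
        return out

    periods = _truncated_normal(params.mean_period, params.period_sd, n_breaths, 0.0)
    factors = _truncated_normal(1.0, params.amplitude_rel_sd, n_breaths, 0.0)
    if params.smoothing_window > 1:
        periods = uniform_filter1d(periods, params.smoothing_window, mode="nearest")
        factors = uniform_filter1d(factors, params.smoothing_window, mode="nearest")
    return periods, factors


def _accumulated_phase(times: np.ndarray, breath_starts: np.ndarray,
                       periods: np.ndarray) -> np.ndarray:
    """Breathing phase in cycles at each time; advances by 1 per breath."""
    idx = np.clip(np.searchsorted(breath_starts, times, side="right") - 1,
                  0, len(periods) - 1)
    frac = (times - breath_starts[idx]) / periods[idx]
    return idx + frac


def generate_trace(params: BreathingParameters) -> MotionTrace:
    """Generate one stochastic phantom motion trace.

    A single accumulated phase (pi of waveform argument per breath) drives
    all channels, so phase-shifted channels stay continuous across breath
    boundaries.  X and Y are always in phase; Z is shifted by
    ``phase_shift_z`` and the surrogate channel by ``surrogate_phase_shift``.
    The per-breath amplitude factor is linearly interpolated between breath
    starts.  Baseline drift (a raised-cosine of peak 3D magnitude
    ``drift_amplitude``) is applied to the three target axes only.  Each
    channel is registered to zero temporal mean.
    """
    rng = np.random.default_rng(params.seed)
    periods, factors = generate_breath_sequence(params, rng=rng)
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    if starts[-1] + periods[-1] < params.duration:
        raise ValueError("breath sequence does not cover the requested duration")

    n_samples = int(np.floor(params.duration / params.sample_interval)) + 1
    times = np.arange(n_samples) * params.sample_interval
    phase_cycles = _accumulated_phase(times, starts, periods)
    theta = np.pi * phase_cycles  # waveform argument

    amp = np.interp(times, starts, factors)
    if not params.shared_amplitude_factor:
        # independent per-axis factors drawn with the same statistics
        amps = []
        for _ in range(3):
            _, f = generate_breath_sequence(params, rng=rng, n_breaths=len(periods))
            amps.append(np.interp(times, starts, f))
        amp_x, amp_y, amp_z = amps
    else:
        amp_x = amp_y = amp_z = amp

    two_n = 2 * int(params.n)
    x = params.mean_amplitude_x * amp_x * np.sin(theta) ** two_n
    y = params.mean_amplitude_y * amp_y * np.sin(theta) ** two_n
    z = params.mean_amplitude_z * amp_z * np.sin(
        theta - phase_fraction_to_radians(params.phase_shift_z)) ** two_n
    s = params.surrogate_mean_amplitude * amp * np.sin(
        theta - phase_fraction_to_radians(params.surrogate_phase_shift)) ** two_n

    if params.drift_amplitude > 0:
        # raised cosine from 0 to drift_amplitude (3D magnitude), split
        # isotropically over the three target axes
        d = 0.5 * params.drift_amplitude * (1 - np.cos(2 * np.pi * times / params.drift_period))
        d_axis = d / np.sqrt(3.0)
        x = x + d_axis
        y = y + d_axis
        z = z + d_axis

    x = x - x.mean()
    y = y - y.mean()
    z = z - z.mean()
    s = s - s.mean()

    meta = {"params": params}
    return MotionTrace(times=times, x=x, y=y, z=z, s=s,
                       cum_phase=phase_cycles, metadata=meta)


def rms_displacement_from_origin(trace: MotionTrace) -> float:
    """3D RMS displacement (mm) from the mean-registered origin:
    ``sqrt(mean(x^2 + y^2 + z^2))``."""
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    return float(np.sqrt(np.mean(trace.x ** 2 + trace.y ** 2 + trace.z ** 2)))


def resample_trace(trace: MotionTrace, interval: float) -> MotionTrace:
    """Linearly interpolate the trace onto a new uniform grid.

    Used to match the motion trace to the LED camera acquisition rate
    (~12.5 ms) before comparing with the tracking log.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    t0, t1 = trace.span()
    if interval > t1 - t0:
        raise ValueError("interval exceeds the trace time span")
    n = int(np.floor((t1 - t0) / interval)) + 1
    new_t = t0 + np.arange(n) * interval
    channels = {name: np.interp(new_t, trace.times, getattr(trace, name))
                for name in ("x", "y", "z", "s")}
    cum = (np.interp(new_t, trace.times, trace.cum_phase)
           if trace.cum_phase is not None else None)
    return MotionTrace(times=new_t, cum_phase=cum, metadata=dict(trace.metadata),
                       **channels)


@dataclass
class MotionLimitReport:
    y_peak_to_peak: float
    jaw_width: float
    passed: bool


def validate_motion_limits(trace: MotionTrace, jaw_width: float = 25.0) -> MotionLimitReport:
    """Check that longitudinal (Y) motion fits under the jaw width.

    Treatment with the 2.5 cm jaw requires Y peak-to-peak motion below
    about 2.5 cm with the target aligned to the mean position.
    """
    if jaw_width <= 0:
        raise ValueError("jaw_width must be positive")
    p2p = float(trace.y.max() - trace.y.min())
    return MotionLimitReport(y_peak_to_peak=p2p, jaw_width=float(jaw_width),
                             passed=p2p < jaw_width)


_TRACE_COLUMNS = ["time_s", "x_mm", "y_mm", "z_mm", "s_mm"]


def write_trace_csv(trace: MotionTrace, path) -> None:
    """Write a trace as CSV with header ``time_s,x_mm,y_mm,z_mm,s_mm``."""
    df = pd.DataFrame({
        "time_s": trace.times, "x_mm": trace.x, "y_mm": trace.y,
        "z_mm": trace.z, "s_mm": trace.s,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path) -> MotionTrace:
    df = pd.read_csv(path)
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return MotionTrace(times=df["time_s"].to_numpy(), x=df["x_mm"].to_numpy(),
                       y=df["y_mm"].to_numpy(), z=df["z_mm"].to_numpy(),
                       s=df["s_mm"].to_numpy())
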