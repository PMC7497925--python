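"""Delivery timeline geometry: gantry rotation, kV acquisition schedule,
LED sampling, and breathing/imaging aliasing diagnostics.

During a helical delivery the gantry rotates continuously and the kV
subsystem acquires a user-chosen number of radiographs per rotation (3-5
typical).  When the time between radiographs approaches the breathing
period, the images repeatedly sample one phase of respiration and the
motion model cannot be built; ``images_per_respiration`` and
``aliasing_index`` quantify that failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .breathing import MotionTrace

__all__ = [
    "DeliveryConfig",
    "KvFix",
    "kv_schedule",
    "images_per_respiration",
    "respiratory_phase_at",
    "aliasing_index",
]


@dataclass
class DeliveryConfig:
    """Parameters of the delivery timeline and tracking loop."""

    treatment_duration: float
    gantry_period: float = 12.0
    kv_per_rotation: int = 4
    led_interval: float = 0.0125
    jaw_width_iso: float = 25.0
    couch_speed: float = 0.5  # mm/s, longitudinal sweep
    kv_noise_sd: float = 0.3  # mm, isotropic localization noise
    kv_latency: float = 0.0   # s, delay between acquisition and model use
    model_window: int = 10    # fixes retained for model fitting
    warmup_fixes: int = 8     # fixes needed before predictions are valid
    fit_residual_threshold: float = 3.0  # mm, flags low-quality models

    def __post_init__(self) -> None:
        if self.treatment_duration <= 0:
            raise ValueError("treatment_duration must be positive")
        if self.gantry_period <= 0:
            raise ValueError("gantry_period must be positive")
        if self.kv_per_rotation < 1:
            raise ValueError("kv_per_rotation must be >= 1")
        if self.led_interval <= 0:
            raise ValueError("led_interval must be positive")
        if self.model_window < 2:
            raise ValueError("model_window must be >= 2")
        if self.warmup_fixes < 2:
            raise ValueError("warmup_fixes must be >= 2")


@dataclass
class KvFix:
    """One emulated kV target localization."""

    time: float
    gantry_angle: float
    measured_position: np.ndarray  # (3,) mm, with localization noise
    true_position: np.ndarray      # (3,) mm, interpolated from the trace
    surrogate_value: Optional[float] = None


def kv_schedule(config: DeliveryConfig):
    """Acquisition times and gantry angles for the kV radiographs.

    ``kv_per_rotation`` acquisitions per gantry rotation, evenly spaced in
    time (hence in angle, starting one spacing after t=0); the schedule
    stops at ``treatment_duration`` inclusive, giving
    ``floor(duration * kv_per_rotation / gantry_period)`` fixes.

    Returns
    -------
    times, angles : ndarray
        Seconds and degrees in [0, 360).
    """
    spacing = config.gantry_period / config.kv_per_rotation
    n = int(np.floor(config.treatment_duration / spacing))
    times = spacing * np.arange(1, n + 1)
    angles = (360.0 * times / config.gantry_period) % 360.0
    return times, angles


def images_per_respiration(mean_period: float, gantry_period: float,
                           kv_per_rotation: int) -> float:
    """Ratio of the breathing period to the average time between kV images.

    Values near 1 indicate that roughly one image is acquired per
    respiration, the configuration prone to phase aliasing.
    """
    if mean_period <= 0 or gantry_period <= 0 or kv_per_rotation <= 0:
        raise ValueError("all arguments must be positive")
    return mean_period / (gantry_period / kv_per_rotation)


def respiratory_phase_at(trace: MotionTrace, times) -> np.ndarray:
    """Breathing phase (cycle fraction in [0, 1)) at the query times.

    The phase is the accumulated breath phase modulo one cycle, linearly
    interpolated from the trace's phase record.
    """
    if trace.cum_phase is None:
        raise ValueError("trace carries no accumulated-phase record")
    times = np.asarray(times, dtype=float)
    t0, t1 = trace.span()
    if np.any(times < t0 - 1e-9) or np.any(times > t1 + 1e-9):
        raise ValueError("query times fall outside the trace span")
    return np.interp(times, trace.times, trace.cum_phase) % 1.0


def aliasing_index(phases: Sequence[float]) -> float:
    """Circular mean resultant length of breathing phases at acquisition.

    Phases (cycle fractions) are mapped to angles on the unit circle;
    the resultant length is 1 when every image samples the same phase
    (fully aliased) and near 0 when phases cover the cycle evenly.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("need at least two phases")
    z = np.exp(2j * np.pi * phases)
    return float(np.abs(z.mean()))
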