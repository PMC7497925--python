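"""Tracking-error statistics: delta_RMS, delta quantiles and cumulative
error curves of the predicted-vs-true position log."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .tracker import TrackedTrace

__all__ = [
    "TrackingErrorSummary",
    "error_series",
    "delta_rms",
    "delta_quantile",
    "cumulative_error_curve",
    "summarize_tracking",
]


def error_series(tracked: TrackedTrace, valid_only: bool = True) -> np.ndarray:
    """Per-sample 3D tracking-error magnitude |predicted - true| in mm.

    By default only samples where the motion model was valid enter the
    statistics (the pre-model warmup is excluded).
    """
    err = np.linalg.norm(tracked.predicted - tracked.true, axis=1)
    if valid_only:
        err = err[tracked.model_valid]
    if err.size == 0:
        raise ValueError("no valid samples in the tracking log")
    return err


def delta_rms(errors) -> float:
    """Root-mean-square of the error magnitudes (mm)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error series")
    return float(np.sqrt(np.mean(errors ** 2)))


def delta_quantile(errors, q: float) -> float:
    """Empirical quantile of the error magnitudes, nearest-rank convention.

    delta_quantile(e, 0.95) is the error not exceeded for 95% of the
    treatment time.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error series")
    if not 0 < q <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    idx = int(np.ceil(q * errors.size)) - 1
    return float(np.sort(errors)[idx])


def cumulative_error_curve(errors, n_grid: int = 200):
    """Probability of observing a tracking error greater than each value.

    Returns (error_mm, prob_exceed) arrays; the curve equals 1 - ECDF
    evaluated on a uniform grid from 0 to the maximum error.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error series")
    grid = np.linspace(0.0, errors.max(), n_grid)
    sorted_err = np.sort(errors)
    prob = 1.0 - np.searchsorted(sorted_err, grid, side="right") / errors.size
    return grid, prob


@dataclass
class TrackingErrorSummary:
    delta_rms: float
    delta_50: float
    delta_95: float
    n_samples: int
    curve: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.delta_50 > self.delta_95 + 1e-12:
            raise ValueError("delta_50 cannot exceed delta_95")

    def to_dict(self) -> dict:
        return {"delta_rms_mm": self.delta_rms, "delta_50_mm": self.delta_50,
                "delta_95_mm": self.delta_95, "n_samples": self.n_samples}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize_tracking(tracked: TrackedTrace, valid_only: bool = True,
                       with_curve: bool = False) -> TrackingErrorSummary:
    """Compute the standard per-case error summary from a tracking log."""
    err = error_series(tracked, valid_only=valid_only)
    return TrackingErrorSummary(
        delta_rms=delta_rms(err),
        delta_50=delta_quantile(err, 0.5),
        delta_95=delta_quantile(err, 0.95),
        n_samples=int(err.size),
        curve=cumulative_error_curve(err) if with_curve else None,
    )


def write_curve_csv(curve, path) -> None:
    """Write a cumulative error curve as ``error_mm,prob_exceed`` CSV."""
    grid, prob = curve
    pd.DataFrame({"error_mm": grid, "prob_exceed": prob}).to_csv(
        path, index=False, float_format="%.6f")
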