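"""Time-resolved dose accumulation for a simplified helical delivery.

The delivery is modelled as a separable dose kernel — a flat-topped jaw
profile (erf-blurred trapezoid, FWHM = jaw width) sweeping longitudinally
with the couch, times a transverse Gaussian conforming to the target —
deposited step by step while the phantom translates rigidly.  Scoring is
in the phantom frame, so at each step the kernel lands shifted by the
instantaneous effective displacement.  This parametric model preserves the
mechanisms under study (finite jaw width, couch sweep, time-modulated
output, motion interplay and blurring) without a treatment-planning
system: dosimetric comparisons made with it are model-level, not
plan-level.  Dose is in normalized units (static dose at the target
center = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.special import erf

__all__ = [
    "DoseGrid",
    "DeliveryPlan",
    "DeliverySequence",
    "DetectorGeometry",
    "build_delivery_sequence",
    "accumulate_dose",
    "add_kv_dose",
    "subtract_kv_dose",
    "extract_profile",
    "penumbra_width",
    "sample_detector",
]


@dataclass
class DoseGrid:
    """3D dose array with origin/spacing metadata (phantom frame).

    ``values[i, j, k]`` is the dose at ``origin + (i*dx, j*dy, k*dz)``.
    """

    origin: np.ndarray   # (3,) mm
    spacing: np.ndarray  # (3,) mm
    values: np.ndarray   # (nx, ny, nz), normalized dose
    frame: str = "phantom"
    truncated: bool = False

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.values.shape[axis])

    @property
    def integral(self) -> float:
        """Integral dose (value sum times voxel volume)."""
        return float(self.values.sum() * np.prod(self.spacing))

    def copy_with(self, values: np.ndarray, **kw) -> "DoseGrid":
        return DoseGrid(origin=self.origin.copy(), spacing=self.spacing.copy(),
                        values=values, frame=self.frame,
                        truncated=kw.get("truncated", self.truncated))

    def interpolator(self) -> RegularGridInterpolator:
        axes = [self.axis_coords(a) for a in range(3)]
        return RegularGridInterpolator(axes, self.values, bounds_error=False,
                                       fill_value=0.0)

    def save(self, path) -> None:
        path = str(path)
        if path.endswith(".h5") or path.endswith(".hdf5"):
            import h5py
            with h5py.File(path, "w") as fh:
                fh.create_dataset("dose", data=self.values)
                fh.attrs["origin_mm"] = self.origin
                fh.attrs["spacing_mm"] = self.spacing
                fh.attrs["frame"] = self.frame
                fh.attrs["truncated"] = self.truncated
        else:
            np.savez(path, dose=self.values, origin_mm=self.origin,
                     spacing_mm=self.spacing, frame=np.bytes_(self.frame),
                     truncated=self.truncated)

    @classmethod
    def load(cls, path) -> "DoseGrid":
        path = str(path)
        if path.endswith(".h5") or path.endswith(".hdf5"):
            import h5py
            with h5py.File(path, "r") as fh:
                return cls(origin=fh.attrs["origin_mm"],
                           spacing=fh.attrs["spacing_mm"],
                           values=fh["dose"][()],
                           frame=str(fh.attrs.get("frame", "phantom")),
                           truncated=bool(fh.attrs.get("truncated", False)))
        data = np.load(path if path.endswith(".npz") else path + ".npz")
        return cls(origin=data["origin_mm"], spacing=data["spacing_mm"],
                   values=data["dose"],
                   frame=data["frame"].item().decode()
                   if "frame" in data else "phantom",
                   truncated=bool(data["truncated"]))


def default_grid(spacing: float = 2.0,
                 extent: tuple = (120.0, 160.0, 120.0)) -> DoseGrid:
    """Empty dose grid centred on the origin (extent in mm per axis)."""
    shape = tuple(int(round(e / spacing)) + 1 for e in extent)
    origin = -np.array(extent) / 2.0
    return DoseGrid(origin=origin, spacing=np.full(3, spacing),
                    values=np.zeros(shape))


@dataclass
class DeliveryPlan:
    """Parameters of the simplified helical delivery."""

    duration: float                 # s, beam-on time
    couch_speed: float = 0.5        # mm/s longitudinal sweep
    gantry_period: float = 12.0     # s
    time_step: float = 0.1          # s
    jaw_fwhm: float = 25.0          # mm, longitudinal field width
    jaw_penumbra_sigma: float = 3.0  # mm
    transverse_sigma: float = 8.0   # mm, target-conformal aperture width
    modulation: str = "uniform"     # "uniform" | "checkerboard"
    modulation_period: float = 5.0  # s, on/off half-cycle for checkerboard
    target_center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.time_step <= 0:
            raise ValueError("duration and time_step must be positive")
        if self.modulation not in ("uniform", "checkerboard"):
            raise ValueError(f"unknown modulation preset {self.modulation!r}")


@dataclass
class DeliverySequence:
    """Per-step beam state: couch (Y) position, gantry angle, output."""

    times: np.ndarray          # step midpoints, s
    beam_center_y: np.ndarray  # mm
    gantry_angle: np.ndarray   # degrees
    output: np.ndarray         # per-step deposited dose scale
    plan: DeliveryPlan

    @property
    def time_step(self) -> float:
        return self.plan.time_step

    @property
    def couch_travel(self) -> float:
        return self.plan.couch_speed * self.plan.duration


def _jaw_profile(y: np.ndarray, fwhm: float, sigma: float) -> np.ndarray:
    """Flat-topped longitudinal profile: erf-blurred slit of width *fwhm*."""
    a = fwhm / 2.0
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((y + a) / s) - erf((y - a) / s))


def build_delivery_sequence(plan: DeliveryPlan,
                            grid: Optional[DoseGrid] = None) -> DeliverySequence:
    """Discretize the helical delivery into uniform time steps.

    The beam centre sweeps the target longitudinally at ``couch_speed``,
    centred on the target; per-step output follows the modulation preset
    and is normalized so that the *static* accumulated dose equals 1.0 at
    the target centre.  With *grid* given, a sweep that leaves the grid
    raises an error.
    """
    n = int(round(plan.duration / plan.time_step))
    if n < 1:
        raise ValueError("duration shorter than one time step")
    times = (np.arange(n) + 0.5) * plan.time_step
    travel = plan.couch_speed * plan.duration
    y0 = plan.target_center[1] - travel / 2.0
    beam_y = y0 + plan.couch_speed * times
    angles = (360.0 * times / plan.gantry_period) % 360.0

    if plan.modulation == "uniform":
        output = np.ones(n)
    else:  # checkerboard in time: alternating on/off blocks
        output = ((times // plan.modulation_period) % 2 == 0).astype(float)
        if output.sum() == 0:
            raise ValueError("modulation pattern leaves no beam-on time")

    if grid is not None:
        ylo, yhi = grid.axis_coords(1)[0], grid.axis_coords(1)[-1]
        if beam_y.min() < ylo or beam_y.max() > yhi:
            raise ValueError("couch sweep extends beyond the dose grid")

    # normalize so the static dose at the target centre is exactly 1
    center_dose = np.sum(output * _jaw_profile(
        plan.target_center[1] - beam_y, plan.jaw_fwhm, plan.jaw_penumbra_sigma))
    if center_dose <= 0:
        raise ValueError("target centre receives no dose; check sweep range")
    output = output / center_dose
    return DeliverySequence(times=times, beam_center_y=beam_y,
                            gantry_angle=angles, output=output, plan=plan)


def accumulate_dose(sequence: DeliverySequence,
                    displacements: Optional[np.ndarray],
                    grid: Optional[DoseGrid] = None) -> DoseGrid:
    """Accumulate dose over the delivery with rigid phantom motion.

    *displacements* is an (N, 3) series of effective target displacement
    at the sequence time steps (None or zeros for a static delivery; the
    full motion trace for an uncompensated delivery; the compensation
    residual for a tracked delivery).  In the phantom frame the beam
    appears shifted by minus the displacement.
    """
    if grid is None:
        grid = default_grid()
    n = len(sequence.times)
    if displacements is None:
        displacements = np.zeros((n, 3))
    displacements = np.asarray(displacements, dtype=float)
    if displacements.shape != (n, 3):
        raise ValueError(f"displacements must have shape ({n}, 3)")

    plan = sequence.plan
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    cx, _, cz = plan.target_center
    dose = np.zeros(grid.values.shape)
    truncated = False
    margin = 3 * max(plan.transverse_sigma, plan.jaw_penumbra_sigma)
    for t in range(n):
        if sequence.output[t] == 0.0:
            continue
        kx = cx - displacements[t, 0]
        ky = sequence.beam_center_y[t] - displacements[t, 1]
        kz = cz - displacements[t, 2]
        if (kx < xs[0] - margin or kx > xs[-1] + margin or
                kz < zs[0] - margin or kz > zs[-1] + margin):
            truncated = True
        fx = np.exp(-0.5 * ((xs - kx) / plan.transverse_sigma) ** 2)
        fy = _jaw_profile(ys - ky, plan.jaw_fwhm, plan.jaw_penumbra_sigma)
        fz = np.exp(-0.5 * ((zs - kz) / plan.transverse_sigma) ** 2)
        dose += sequence.output[t] * fx[:, None, None] * fy[None, :, None] * fz[None, None, :]
    if truncated:
        warnings.warn("beam kernel partially off-grid during the delivery; "
                      "dose is truncated", stacklevel=2)
    return DoseGrid(origin=grid.origin.copy(), spacing=grid.spacing.copy(),
                    values=dose, frame=grid.frame, truncated=truncated)


def add_kv_dose(grid: DoseGrid, n_images: int,
                kv_dose_per_image: float) -> DoseGrid:
    """Add the diode response to the kV radiographs (uniform per image)."""
    if kv_dose_per_image < 0:
        raise ValueError("kv_dose_per_image must be >= 0")
    return grid.copy_with(grid.values + n_images * kv_dose_per_image)


def subtract_kv_dose(grid: DoseGrid, n_images: int,
                     kv_dose_per_image: float) -> DoseGrid:
    """Exact inverse of :func:`add_kv_dose`; clips negatives to 0 with a
    warning (mirrors subtracting a measured kV-only delivery)."""
    if kv_dose_per_image < 0:
        raise ValueError("kv_dose_per_image must be >= 0")
    out = grid.values - n_images * kv_dose_per_image
    if np.any(out < 0):
        warnings.warn("kV-dose subtraction produced negative dose; clipping "
                      "to zero", stacklevel=2)
        out = np.clip(out, 0.0, None)
    return grid.copy_with(out)


def extract_profile(grid: DoseGrid, axis: str):
    """1D dose profile along X, Y or Z through the geometric grid centre.

    The nearest grid line is used, with ties broken toward the lower
    index.  Returns (positions_mm, dose).
    """
    axis_idx = {"x": 0, "y": 1, "z": 2}.get(str(axis).lower())
    if axis_idx is None:
        raise ValueError("axis must be one of X, Y, Z")
    if min(grid.values.shape) < 2:
        raise ValueError("degenerate dose grid")
    centers = [(s - 1) // 2 for s in grid.values.shape]
    index = [slice(None) if a == axis_idx else centers[a] for a in range(3)]
    return grid.axis_coords(axis_idx), grid.values[tuple(index)]


def penumbra_width(positions: np.ndarray, dose: np.ndarray,
                   low: float = 0.2, high: float = 0.8) -> float:
    """Mean 20-80% penumbra width (mm) of a single-peaked profile.

    Measured on both flanks of the profile relative to its maximum, by
    linear interpolation of the crossing positions; returns the average of
    the two flanks.
    """
    dose = np.asarray(dose, dtype=float)
    peak = dose.max()
    if peak <= 0:
        raise ValueError("profile has no dose")
    ipk = int(np.argmax(dose))

    def crossing(side_pos, side_dose, level):
        target = level * peak
        d = side_dose - target
        sign = np.sign(d)
        idx = np.where(np.diff(sign) != 0)[0]
        if len(idx) == 0:
            return None
        i = idx[-1] if side_dose[0] < target else idx[0]
        x0, x1 = side_pos[i], side_pos[i + 1]
        y0, y1 = side_dose[i], side_dose[i + 1]
        return x0 + (target - y0) * (x1 - x0) / (y1 - y0)

    widths = []
    left = slice(0, ipk + 1)
    right = slice(ipk, None)
    for sl in (left, right):
        lo = crossing(positions[sl], dose[sl], low)
        hi = crossing(positions[sl], dose[sl], high)
        if lo is not None and hi is not None:
            widths.append(abs(hi - lo))
    if not widths:
        raise ValueError("could not locate 20/80% crossings on either flank")
    return float(np.mean(widths))


@dataclass
class DetectorGeometry:
    """Two orthogonal planar diode arrays through the phantom centre.

    The central region has fine diode spacing (2.5 mm), the periphery
    coarse spacing (5 mm).  Plane A lies in the X-Y plane (z = 0), plane B
    in the Z-Y plane (x = 0).
    """

    central_spacing: float = 2.5
    peripheral_spacing: float = 5.0
    central_halfwidth: float = 20.0
    halfwidth: float = 50.0

    def __post_init__(self) -> None:
        if self.central_spacing <= 0 or self.peripheral_spacing <= 0:
            raise ValueError("diode spacings must be positive")
        if not 0 < self.central_halfwidth <= self.halfwidth:
            raise ValueError("central region must fit inside the detector")

    def _coords_1d(self) -> np.ndarray:
        fine = np.arange(-self.central_halfwidth, self.central_halfwidth + 1e-9,
                         self.central_spacing)
        coarse_hi = np.arange(self.central_halfwidth + self.peripheral_spacing,
                              self.halfwidth + 1e-9, self.peripheral_spacing)
        return np.concatenate([-coarse_hi[::-1], fine, coarse_hi])

    def diode_positions(self) -> np.ndarray:
        """(P, 3) diode coordinates of both planes, mm."""
        u = self._coords_1d()
        uu, vv = np.meshgrid(u, u, indexing="ij")
        plane_a = np.column_stack([uu.ravel(), vv.ravel(), np.zeros(uu.size)])
        plane_b = np.column_stack([np.zeros(uu.size), vv.ravel(), uu.ravel()])
        return np.vstack([plane_a, plane_b])


def sample_detector(grid: DoseGrid, det: Optional[DetectorGeometry] = None):
    """Trilinear interpolation of the dose grid at the diode positions.

    Returns (positions (P, 3), readings (P,), in_grid mask).  Diodes
    outside the grid are flagged and read zero.
    """
    if det is None:
        det = DetectorGeometry()
    pos = det.diode_positions()
    lo = np.array([grid.axis_coords(a)[0] for a in range(3)])
    hi = np.array([grid.axis_coords(a)[-1] for a in range(3)])
    in_grid = np.all((pos >= lo) & (pos <= hi), axis=1)
    readings = grid.interpolator()(pos)
    return pos, readings, in_grid


def write_profile_csv(positions, dose, path) -> None:
    pd.DataFrame({"pos_mm": positions, "dose": dose}).to_csv(
        path, index=False, float_format="%.6f")
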