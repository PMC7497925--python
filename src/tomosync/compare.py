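"""Dose-comparison statistics: global gamma index (TG-218 style criteria),
median dose difference above a threshold, and the paired t-test used for
population comparisons.

The gamma index combines a dose-difference criterion (percent of the
global maximum reference dose) with a distance-to-agreement criterion: for
every reference point above the low-dose threshold,

    gamma(p) = min over r of sqrt( (D_eval(p+r) - D_ref(p))^2 / dD^2
                                   + |r|^2 / dta^2 ),

with the evaluated dose interpolated on a fine step inside a bounded
search radius.  A point passes when gamma <= 1.  Gamma is directional:
reference and evaluated roles are not interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from scipy import stats

from .dose import DoseGrid

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_pass_rate",
    "median_dose_difference",
    "paired_t_test",
]

PointSet = Tuple[np.ndarray, np.ndarray]  # (positions (P,3) mm, values (P,))


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria; defaults are the TG-218 global 3%/2 mm with a 10%
    low-dose threshold."""

    dose_percent: float = 3.0
    distance_mm: float = 2.0
    threshold_percent: float = 10.0
    search_radius: Optional[float] = None  # default 3 * distance_mm
    interp_step: float = 0.2  # mm

    def __post_init__(self) -> None:
        if min(self.dose_percent, self.distance_mm, self.interp_step) <= 0:
            raise ValueError("criteria must be positive")
        if not 0 <= self.threshold_percent < 100:
            raise ValueError("threshold_percent must lie in [0, 100)")
        if self.search_radius is None:
            object.__setattr__(self, "search_radius", 3.0 * self.distance_mm)


@dataclass
class GammaResult:
    pass_rate: float           # percent of evaluated points with gamma <= 1
    gamma: np.ndarray          # per above-threshold reference point
    n_evaluated: int
    criteria: GammaCriteria
    reference_max: float

    def __post_init__(self) -> None:
        if not 0 <= self.pass_rate <= 100:
            raise ValueError("pass rate must lie in [0, 100]")


def _as_points(obj: Union[DoseGrid, PointSet]) -> PointSet:
    if isinstance(obj, DoseGrid):
        ax = [obj.axis_coords(a) for a in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return (np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]),
                obj.values.ravel())
    pos, val = obj
    return np.asarray(pos, dtype=float), np.asarray(val, dtype=float)


def _offset_shells(radius: float, step: float):
    """Displacement offsets within *radius* grouped into distance shells."""
    n = int(np.floor(radius / step))
    axis = step * np.arange(-n, n + 1)
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    dist = np.linalg.norm(offsets, axis=1)
    keep = (dist <= radius) & (dist > 0)
    offsets, dist = offsets[keep], dist[keep]
    order = np.argsort(dist)
    offsets, dist = offsets[order], dist[order]
    # shells one interpolation step thick
    shell_id = np.floor(dist / step + 1e-9).astype(int)
    shells = []
    for sid in np.unique(shell_id):
        m = shell_id == sid
        shells.append((dist[m].min(), offsets[m]))
    return shells


def gamma_pass_rate(reference: Union[DoseGrid, PointSet], evaluated: DoseGrid,
                    criteria: Optional[GammaCriteria] = None) -> GammaResult:
    """Global gamma analysis of *evaluated* against *reference*.

    *reference* may be a dose grid (every voxel becomes a reference point)
    or a point set such as diode readings; *evaluated* is a dose grid
    interpolated trilinearly during the distance search.  Normalization is
    global: the dose criterion is a percent of the maximum reference dose.
    """
    if criteria is None:
        criteria = GammaCriteria()
    ref_pos, ref_val = _as_points(reference)
    maxref = float(ref_val.max())
    if maxref <= 0:
        raise ValueError("reference maximum dose must be positive")
    mask = ref_val >= criteria.threshold_percent / 100.0 * maxref
    if not np.any(mask):
        raise ValueError("no reference points above the dose threshold")
    pos = ref_pos[mask]
    val = ref_val[mask]

    dose_tol = criteria.dose_percent / 100.0 * maxref
    dta = criteria.distance_mm
    interp = evaluated.interpolator()

    gamma_sq = ((interp(pos) - val) / dose_tol) ** 2
    active = np.arange(len(pos))
    for r_min, offsets in _offset_shells(criteria.search_radius,
                                         criteria.interp_step):
        if active.size == 0:
            break
        dist_term = (r_min / dta) ** 2
        active = active[gamma_sq[active] > dist_term]
        if active.size == 0:
            break
        cand = None
        for chunk in np.array_split(offsets, max(1, offsets.shape[0] // 512)):
            pts = pos[active, None, :] + chunk[None, :, :]
            d = interp(pts.reshape(-1, 3)).reshape(active.size, -1)
            g = ((d - val[active, None]) / dose_tol) ** 2 \
                + (np.linalg.norm(chunk, axis=1)[None, :] / dta) ** 2
            gmin = g.min(axis=1)
            cand = gmin if cand is None else np.minimum(cand, gmin)
        gamma_sq[active] = np.minimum(gamma_sq[active], cand)

    gamma = np.sqrt(gamma_sq)
    pass_rate = 100.0 * float(np.mean(gamma <= 1.0 + 1e-9))
    return GammaResult(pass_rate=pass_rate, gamma=gamma,
                       n_evaluated=int(mask.sum()), criteria=criteria,
                       reference_max=maxref)


def median_dose_difference(reference: Union[DoseGrid, PointSet],
                           evaluated: Union[DoseGrid, PointSet],
                           threshold_percent: float = 50.0) -> float:
    """Median of (evaluated - reference) over reference points above the
    threshold, as a percent of the global maximum reference dose.

    Positive means the evaluated dose is hotter than the reference in the
    high-dose region.
    """
    ref_pos, ref_val = _as_points(reference)
    maxref = float(ref_val.max())
    if maxref <= 0:
        raise ValueError("reference maximum dose must be positive")
    mask = ref_val >= threshold_percent / 100.0 * maxref
    if not np.any(mask):
        raise ValueError("no reference points above the dose threshold")
    if isinstance(evaluated, DoseGrid):
        ev = evaluated.interpolator()(ref_pos[mask])
    else:
        ev_pos, ev_val = _as_points(evaluated)
        if ev_pos.shape != ref_pos.shape or not np.allclose(ev_pos, ref_pos):
            raise ValueError("point-set comparison requires matching positions")
        ev = ev_val[mask]
    return float(np.median(ev - ref_val[mask]) / maxref * 100.0)


def paired_t_test(series_a, series_b) -> Tuple[float, float]:
    """Two-tailed paired t-test; returns (t statistic, p value).

    Raises on zero-variance differences (the t statistic is undefined).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1D series with n >= 2")
    if np.allclose(a - b, (a - b)[0]):
        raise ValueError("degenerate paired t-test: zero-variance differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
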