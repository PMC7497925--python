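"""Per-case study orchestration: trace -> tracking -> scenario doses ->
comparisons, mirroring a delivery-QA measurement session.

The packaged case configs describe the 13 subject motion cases (lung,
liver, pancreas) and the 9 surrogate-stage variants of the Lung 5 case in
which the LED surrogate moves separately from the target.  Three delivery
scenarios are simulated per case: M0S0 (static phantom), M1S0 (motion, no
tracking) and M1S1 (motion with tracking compensation).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .breathing import BreathingParameters, MotionTrace, generate_trace
from .compare import GammaCriteria, gamma_pass_rate, median_dose_difference, paired_t_test
from .delivery import DeliveryConfig, aliasing_index, images_per_respiration, kv_schedule, respiratory_phase_at
from .dose import DeliveryPlan, DetectorGeometry, DoseGrid, accumulate_dose, build_delivery_sequence, default_grid, sample_detector
from .metrics import TrackingErrorSummary, summarize_tracking
from .tracker import TrackedTrace, compensation_residual, run_tracking

__all__ = [
    "CaseStudy",
    "DoseOptions",
    "CaseResult",
    "StudyReport",
    "available_cases",
    "load_case",
    "case_seed",
    "run_case",
    "run_study",
]

SCENARIOS = ("M0S0", "M1S0", "M1S1")


@dataclass
class CaseStudy:
    """One subject case: breathing parameters plus delivery configuration."""

    case_id: str
    breathing: dict              # BreathingParameters fields (no duration/seed)
    delivery: dict               # DeliveryConfig fields (needs treatment_duration)
    led_mode: str = "phantom"    # "phantom" | "surrogate"
    scenarios: Sequence[str] = SCENARIOS
    reference_rms: Optional[float] = None  # printed 3D RMS, mm (when known)

    def __post_init__(self) -> None:
        if self.led_mode not in ("phantom", "surrogate"):
            raise ValueError("led_mode must be 'phantom' or 'surrogate'")
        bad = set(self.scenarios) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios: {sorted(bad)}")
        if self.led_mode == "surrogate":
            for key in ("surrogate_mean_amplitude", "surrogate_phase_shift"):
                if key not in self.breathing:
                    raise ValueError(
                        f"surrogate-stage case requires breathing.{key}")

    def breathing_parameters(self, seed: int,
                             duration: Optional[float] = None,
                             **overrides) -> BreathingParameters:
        kw = dict(self.breathing)
        kw.update(overrides)
        if duration is None:
            duration = (self.delivery["treatment_duration"]
                        + self.warmup_lead()
                        + 3 * kw.get("mean_period", 4.0))
        return BreathingParameters(duration=duration, seed=seed, **kw)

    def warmup_lead(self) -> float:
        """Pre-beam-on model-building time: the delivery is started only
        once the motion model is valid (the machine pauses to acquire the
        warmup radiographs)."""
        cfg = self.delivery
        spacing = cfg.get("gantry_period", 12.0) / cfg.get("kv_per_rotation", 4)
        return (cfg.get("warmup_fixes", 8) + 1) * spacing

    def delivery_config(self, **overrides) -> DeliveryConfig:
        kw = dict(self.delivery)
        kw.update(overrides)
        return DeliveryConfig(**kw)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "CaseStudy":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            raw = yaml.safe_load(Path(path_or_stream).read_text())
        return cls(case_id=raw["case"], breathing=raw["breathing"],
                   delivery=raw["delivery"],
                   led_mode=raw.get("led_mode", "phantom"),
                   scenarios=tuple(raw.get("scenarios", SCENARIOS)),
                   reference_rms=raw.get("reference_rms"))


def _case_dir():
    return resources.files("tomosync") / "data" / "cases"


def available_cases() -> List[str]:
    return sorted(p.name[:-5] for p in _case_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_case(name: str) -> CaseStudy:
    path = _case_dir() / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown case {name!r}; available: {available_cases()}")
    return CaseStudy.from_yaml(path.open())


def case_seed(master_seed: int, case_id: str) -> int:
    """Stable per-case seed derived from the master seed and case id."""
    return (int(master_seed) * 100_003 + zlib.crc32(case_id.encode())) % (2 ** 31)


@dataclass
class DoseOptions:
    """Desk-scale dose-simulation settings shared by the three scenarios."""

    grid_spacing: float = 2.0
    grid_extent: tuple = (120.0, 160.0, 120.0)
    time_step: float = 0.1
    sweep_extent: float = 60.0    # mm of couch travel across the target
    transverse_sigma: float = 8.0
    jaw_fwhm: float = 25.0
    jaw_penumbra_sigma: float = 3.0
    modulation: str = "uniform"
    modulation_period: float = 5.0
    plan_time_step_divisor: int = 4  # plan-analog runs at time_step / divisor
    along_beam_weight: float = 0.0
    criteria: GammaCriteria = field(default_factory=GammaCriteria)
    median_threshold_percent: float = 50.0
    use_detector_samples: bool = True
    detector: DetectorGeometry = field(default_factory=DetectorGeometry)


@dataclass
class CaseResult:
    case_id: str
    seed: int
    trace: MotionTrace
    tracked: Optional[TrackedTrace]
    tracking_summary: Optional[TrackingErrorSummary]
    images_per_respiration: float
    aliasing_index: float
    doses: Dict[str, DoseGrid] = field(default_factory=dict)
    plan_dose: Optional[DoseGrid] = None
    gamma_vs_m0s0: Dict[str, float] = field(default_factory=dict)
    gamma_vs_plan: Dict[str, float] = field(default_factory=dict)
    median_diff_vs_m0s0: Dict[str, float] = field(default_factory=dict)
    median_diff_vs_plan: Dict[str, float] = field(default_factory=dict)

    def metrics_row(self) -> dict:
        row = {"case": self.case_id, "seed": self.seed,
               "images_per_respiration": self.images_per_respiration,
               "aliasing_index": self.aliasing_index}
        if self.tracking_summary is not None:
            row.update(self.tracking_summary.to_dict())
        for name, d in (("gamma_vs_m0s0", self.gamma_vs_m0s0),
                        ("gamma_vs_plan", self.gamma_vs_plan),
                        ("med_diff_vs_m0s0", self.median_diff_vs_m0s0),
                        ("med_diff_vs_plan", self.median_diff_vs_plan)):
            for scen, v in d.items():
                row[f"{name}_{scen.lower()}"] = v
        return row


def _delivery_plan(case: CaseStudy, opts: DoseOptions,
                   time_step: Optional[float] = None) -> DeliveryPlan:
    duration = case.delivery["treatment_duration"]
    return DeliveryPlan(
        duration=duration,
        couch_speed=opts.sweep_extent / duration,
        gantry_period=case.delivery.get("gantry_period", 12.0),
        time_step=time_step or opts.time_step,
        jaw_fwhm=opts.jaw_fwhm, jaw_penumbra_sigma=opts.jaw_penumbra_sigma,
        transverse_sigma=opts.transverse_sigma,
        modulation=opts.modulation, modulation_period=opts.modulation_period,
    )


def _displacement_at(times: np.ndarray, source_times: np.ndarray,
                     series: np.ndarray) -> np.ndarray:
    return np.column_stack([np.interp(times, source_times, series[:, a])
                            for a in range(3)])


def run_case(case: CaseStudy, seed: int, with_dose: bool = True,
             dose_options: Optional[DoseOptions] = None,
             outdir: Optional[Path] = None) -> CaseResult:
    """Run one case end to end; deterministic for a fixed seed.

    Generates the motion trace, runs the tracking loop (surrogate channel
    selected by the case's LED placement mode), simulates the requested
    delivery scenarios on the dose grid, and compares them with gamma and
    median dose difference (on diode samples by default).  With *outdir*
    set, traces, logs, dose grids and a metrics JSON are written there.
    """
    opts = dose_options or DoseOptions()
    s = case_seed(seed, case.case_id)
    params = case.breathing_parameters(seed=s)
    trace = generate_trace(params)
    # the tracking loop runs through a pre-beam-on warmup lead (the machine
    # builds its model before delivering), then the treatment window
    lead = case.warmup_lead()
    config = case.delivery_config(
        treatment_duration=case.delivery["treatment_duration"] + lead)

    fix_times, _ = kv_schedule(config)
    phases = respiratory_phase_at(trace, fix_times)
    ipr = images_per_respiration(params.mean_period, config.gantry_period,
                                 config.kv_per_rotation)
    alias = aliasing_index(phases)

    tracked = None
    summary = None
    need_tracking = "M1S1" in case.scenarios
    if need_tracking:
        source = "phantom" if case.led_mode == "phantom" else "surrogate"
        tracked = run_tracking(trace, config, surrogate_source=source,
                               seed=s + 1)
        summary = summarize_tracking(tracked)

    result = CaseResult(case_id=case.case_id, seed=seed, trace=trace,
                        tracked=tracked, tracking_summary=summary,
                        images_per_respiration=ipr, aliasing_index=alias)

    if with_dose:
        grid = default_grid(opts.grid_spacing, opts.grid_extent)
        plan = _delivery_plan(case, opts)
        seq = build_delivery_sequence(plan, grid)
        disp = {"M0S0": None}
        beam_times = seq.times + lead  # delivery starts after the warmup
        if "M1S0" in case.scenarios:
            disp["M1S0"] = _displacement_at(beam_times, trace.times,
                                            trace.displacement)
        if "M1S1" in case.scenarios:
            residual = compensation_residual(tracked, opts.along_beam_weight)
            disp["M1S1"] = _displacement_at(beam_times, tracked.times, residual)
        for scen in case.scenarios:
            result.doses[scen] = accumulate_dose(seq, disp.get(scen), grid)

        # plan-analog: the same static delivery at a finer time step
        plan_seq = build_delivery_sequence(
            _delivery_plan(case, opts,
                           time_step=opts.time_step / opts.plan_time_step_divisor),
            grid)
        result.plan_dose = accumulate_dose(plan_seq, None, grid)

        det = opts.detector if opts.use_detector_samples else None

        def _points(g: DoseGrid):
            if det is None:
                return g
            pos, vals, _ = sample_detector(g, det)
            return pos, vals

        ref_static = _points(result.doses["M0S0"]) if "M0S0" in result.doses else None
        ref_plan = _points(result.plan_dose)
        for scen in case.scenarios:
            ev = result.doses[scen]
            result.gamma_vs_plan[scen] = gamma_pass_rate(
                ref_plan, ev, opts.criteria).pass_rate
            result.median_diff_vs_plan[scen] = median_dose_difference(
                ref_plan, ev, opts.median_threshold_percent)
            if scen != "M0S0" and ref_static is not None:
                result.gamma_vs_m0s0[scen] = gamma_pass_rate(
                    ref_static, ev, opts.criteria).pass_rate
                result.median_diff_vs_m0s0[scen] = median_dose_difference(
                    ref_static, ev, opts.median_threshold_percent)

    if outdir is not None:
        _write_case_outputs(result, Path(outdir))
    return result


def _write_case_outputs(result: CaseResult, outdir: Path) -> None:
    from .breathing import write_trace_csv
    from .tracker import write_tracking_log

    outdir.mkdir(parents=True, exist_ok=True)
    slug = result.case_id.lower().replace(" ", "_")
    write_trace_csv(result.trace, outdir / f"{slug}_trace.csv")
    if result.tracked is not None:
        write_tracking_log(result.tracked, outdir / f"{slug}_tracking.csv")
    for scen, grid in result.doses.items():
        grid.save(outdir / f"{slug}_{scen.lower()}.h5")
    with open(outdir / f"{slug}_metrics.json", "w") as fh:
        json.dump(result.metrics_row(), fh, indent=2, default=float)


@dataclass
class StudyReport:
    per_case: pd.DataFrame
    t_tests: Dict[str, dict]
    seed: int

    def summary_row(self) -> pd.Series:
        numeric = self.per_case.select_dtypes("number")
        return pd.Series({c: f"{numeric[c].mean():.1f} ({numeric[c].std():.1f})"
                          for c in numeric.columns}, name="Mean (Std.)")

    def save(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(outdir / "per_case_metrics.csv", index=False)
        with open(outdir / "t_tests.json", "w") as fh:
            json.dump(self.t_tests, fh, indent=2, default=float)
        manifest = {"seed": self.seed, "n_cases": len(self.per_case),
                    "files": ["per_case_metrics.csv", "t_tests.json"]}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def run_study(cases: Sequence[CaseStudy], seed: int, with_dose: bool = True,
              dose_options: Optional[DoseOptions] = None,
              outdir: Optional[Path] = None) -> StudyReport:
    """Run a list of cases and aggregate population statistics.

    Paired two-tailed t-tests compare the M1S0 and M1S1 scenario columns
    (gamma pass rate and median dose difference against the static
    delivery) across cases; degenerate (zero-variance) comparisons are
    reported as such rather than raising.
    """
    if len(cases) < 2:
        raise ValueError("a study needs at least two cases for paired tests")
    rows = []
    for case in cases:
        missing = set(SCENARIOS) - set(case.scenarios)
        if with_dose and missing:
            raise ValueError(f"case {case.case_id} lacks scenarios {missing}")
        res = run_case(case, seed=seed, with_dose=with_dose,
                       dose_options=dose_options)
        rows.append(res.metrics_row())
    df = pd.DataFrame(rows)

    t_tests: Dict[str, dict] = {}
    if with_dose:
        for metric, a_col, b_col in (
                ("gamma_vs_m0s0", "gamma_vs_m0s0_m1s0", "gamma_vs_m0s0_m1s1"),
                ("med_diff_vs_m0s0", "med_diff_vs_m0s0_m1s0",
                 "med_diff_vs_m0s0_m1s1")):
            try:
                t, p = paired_t_test(df[a_col], df[b_col])
                t_tests[metric] = {"t": t, "p": p, "n": len(df),
                                   "degenerate": False}
            except ValueError:
                t_tests[metric] = {"t": None, "p": None, "n": len(df),
                                   "degenerate": True}
    report = StudyReport(per_case=df, t_tests=t_tests, seed=seed)
    if outdir is not None:
        report.save(outdir)
    return report
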