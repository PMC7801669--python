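"""Arterial-spin-labeling perfusion quantification over an
ischemia-reperfusion paradigm.

Tagged/control image pairs yield a perfusion map every 20 s. The relative
difference r = (M - M+)/M between control (M) and tagged (M+) ROI means is
converted to blood flow with the single-compartment saturation model

    f = (lambda / T1m) * r / (exp(-tT/T1a) - r)

with lambda the tissue-blood partition coefficient, T1m the intrinsic muscle
T1, T1a the arterial blood T1 and tT the arterial transit time. With T1m in
minutes and a factor 100 the result is in ml/min/100 g (tissue density
1 g/ml). The paradigm (rest -> cuff ischemia -> reperfusion) is summarized
by the rest baseline, the maximal reperfusion flow, and the total perfusion:
the baseline-subtracted trapezoidal integral of flow over the reperfusion
window (the volume repaid by the hyperaemic response), with per-sample
negative excursions floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PerfusionConstants",
    "PhaseTiming",
    "ASLSeries",
    "PerfusionTrace",
    "PerfusionSummary",
    "asl_to_perfusion",
    "paradigm_summary",
    "perfusion_forward_ratio",
]

PHASES = ("rest", "ischemia", "reperfusion")


@dataclass(frozen=True)
class PerfusionConstants:
    """Scaling constants of the ASL quantification model (SI-ish units: s)."""

    partition_coefficient: float = 0.75  # dimensionless, skeletal muscle
    t1_muscle_s: float = 2.0  # intrinsic muscle T1 without perfusion
    t1_arterial_s: float = 2.2  # arterial blood T1 at 7 T
    transit_time_s: float = 0.2  # tagging slice to imaged voxel

    def __post_init__(self):
        for name in ("partition_coefficient", "t1_muscle_s", "t1_arterial_s", "transit_time_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def inflow_efficiency(self) -> float:
        """exp(-tT/T1a): attenuation of the tag over the transit time."""
        return float(np.exp(-self.transit_time_s / self.t1_arterial_s))

    @property
    def scale_ml_min_100g(self) -> float:
        """lambda/T1m in 1/min, times 100 -> ml/min/100 g prefactor."""
        return self.partition_coefficient / (self.t1_muscle_s / 60.0) * 100.0


@dataclass(frozen=True)
class PhaseTiming:
    """Durations (s) of the rest / ischemia / reperfusion phases."""

    rest_s: float = 200.0  # 3 min 20 s
    ischemia_s: float = 410.0  # 6 min 50 s
    reperfusion_s: float = 640.0  # 10 min 40 s
    map_interval_s: float = 20.0

    def __post_init__(self):
        if min(self.rest_s, self.ischemia_s, self.reperfusion_s) <= 0:
            raise ValueError("phase durations must be positive")
        if self.map_interval_s <= 0:
            raise ValueError("map interval must be positive")

    @property
    def total_s(self) -> float:
        return self.rest_s + self.ischemia_s + self.reperfusion_s

    def sample_times(self) -> np.ndarray:
        """One perfusion sample per 20-s tag/control cycle."""
        return np.arange(0.0, self.total_s, self.map_interval_s)

    def phase_of(self, t_s) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        out = np.where(
            t < self.rest_s,
            "rest",
            np.where(t < self.rest_s + self.ischemia_s, "ischemia", "reperfusion"),
        )
        return out.astype(object)


@dataclass(frozen=True)
class ASLSeries:
    """Paired control/tagged ROI means with timestamps and phase labels."""

    times_s: np.ndarray
    control: np.ndarray  # M
    tagged: np.ndarray  # M+
    phases: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        m = np.asarray(self.control, dtype=float)
        mp = np.asarray(self.tagged, dtype=float)
        ph = np.asarray(self.phases, dtype=object)
        if not (t.shape == m.shape == mp.shape == ph.shape):
            raise ValueError("times, control, tagged and phases must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        unknown = set(ph) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")
        # phases must appear contiguously in paradigm order
        codes = [PHASES.index(p) for p in ph]
        if np.any(np.diff(codes) < 0):
            raise ValueError("phases must be contiguous in rest->ischemia->reperfusion order")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "control", m)
        object.__setattr__(self, "tagged", mp)
        object.__setattr__(self, "phases", ph)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "M_control": self.control,
                "M_tagged": self.tagged,
                "phase": self.phases,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ASLSeries":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["M_control"].to_numpy(),
            df["M_tagged"].to_numpy(),
            df["phase"].to_numpy(),
        )


@dataclass(frozen=True)
class PerfusionTrace:
    """Perfusion time course (ml/min/100 g) with phase labels; NaN where the
    quantification denominator was nonpositive."""

    times_s: np.ndarray
    f_ml_min_100g: np.ndarray
    phases: np.ndarray


@dataclass(frozen=True)
class PerfusionSummary:
    """Paradigm summary: rest baseline, total repaid volume, peak flow."""

    rest_baseline_ml_min_100g: float
    total_perfusion_ml_100g: float
    maximal_perfusion_ml_min_100g: float


def perfusion_forward_ratio(f_ml_min_100g, constants: PerfusionConstants) -> np.ndarray:
    """Invert the quantification model: flow -> relative difference (M-M+)/M.

    Used by the synthetic generator; exact inverse of :func:`asl_to_perfusion`.
    """
    f = np.asarray(f_ml_min_100g, dtype=float)
    if np.any(f < 0):
        raise ValueError("perfusion must be nonnegative")
    g = f / constants.scale_ml_min_100g  # r/(E - r)
    return constants.inflow_efficiency * g / (1.0 + g)


def asl_to_perfusion(series: ASLSeries, constants: PerfusionConstants | None = None) -> PerfusionTrace:
    """Convert a tagged/control series to a perfusion time course.

    Samples whose relative difference reaches the model singularity
    (r >= exp(-tT/T1a)) are flagged NaN with a warning rather than failing
    the whole series.
    """
    constants = constants or PerfusionConstants()
    if np.any(series.control <= 0):
        raise ValueError("control signal M must be positive at every sample")
    r = (series.control - series.tagged) / series.control
    denom = constants.inflow_efficiency - r
    bad = denom <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} ASL sample(s) at or past the model singularity; flagged NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = constants.scale_ml_min_100g * r / denom
    f = np.where(bad, np.nan, f)
    return PerfusionTrace(series.times_s, f, series.phases)


def paradigm_summary(trace: PerfusionTrace) -> PerfusionSummary:
    """Summarize a rest/ischemia/reperfusion perfusion trace.

    baseline = median flow over rest; maximal = max flow during reperfusion;
    total = trapezoidal integral of max(f - baseline, 0) over reperfusion,
    with time in minutes (ml/100 g).
    """
    ph = trace.phases
    for phase in PHASES:
        if not np.any(ph == phase):
            raise ValueError(f"paradigm phase {phase!r} missing from trace")
    rest_f = trace.f_ml_min_100g[ph == "rest"]
    baseline = float(np.nanmedian(rest_f))
    rep = ph == "reperfusion"
    t_rep = trace.times_s[rep]
    f_rep = trace.f_ml_min_100g[rep]
    ok = np.isfinite(f_rep)
    if not np.any(ok):
        raise ValueError("all reperfusion samples are missing; summary undefined")
    excess = np.clip(f_rep[ok] - baseline, 0.0, None)
    total = float(np.trapezoid(excess, t_rep[ok] / 60.0))
    return PerfusionSummary(baseline, total, float(np.nanmax(f_rep)))
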