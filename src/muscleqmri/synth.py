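"""Synthetic data generator for every modality the pipeline consumes.

Since no cohort data are deposited, the generators stand in for the paired
injured/control mouse cohort with *known ground truth*: saturation-recovery
T1 series, MSME/CPMG echo trains, oscillatory UTE decays, tagged/control ASL
series over the ischemia-reperfusion paradigm, shear-modulus angle profiles,
ROI intensity samples with controllable outlier contamination, and a paired
cohort table whose marginals and rank correlations are calibrated to the
reference group medians/IQRs.

Calibration strategy
--------------------
Metrics are positive and reported as median (IQR), so marginals are
log-normal with ``mu = ln(median)`` and ``sigma`` solved from
``IQR = 2*median*sinh(0.6745*sigma)`` (skewness, which can be negative, uses
a normal marginal). Dependence between each metric and collagen fraction is
induced by a Gaussian copula with a single shared latent factor per muscle:
the metric's latent loading is ``2*sin(pi*rho_s/6)`` for a target Spearman
``rho_s``, so realized rank correlations converge to their targets as the
cohort grows. The factor structure keeps the latent correlation matrix
positive semidefinite by construction.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elastography import SWE_ANGLES_DEG, SWEMeasurement
from .perfusion import (
    ASLSeries,
    PerfusionConstants,
    PhaseTiming,
    perfusion_forward_ratio,
)
from .relaxometry import ute_model_amplitude
from .signals import (
    CPMG_ESP_MS,
    CPMG_N_ECHOES,
    RelaxationSignal,
    T1_SR_TR_MS,
    UTE_TE_MS,
)

__all__ = [
    "MarginalSpec",
    "GeneratorPreset",
    "SyntheticCohort",
    "HyperaemiaCurve",
    "PRESETS",
    "get_preset",
    "gen_t1_series",
    "gen_cpmg_signal",
    "gen_ute_signal",
    "gen_asl_series",
    "gen_swe_profile",
    "gen_texture_roi",
    "gen_cohort",
    "spearman_to_latent",
]

_Z75 = 0.6744897501960817  # Phi^{-1}(0.75)


def spearman_to_latent(rho_s: float) -> float:
    """Latent (Pearson) correlation of a Gaussian copula achieving a target
    Spearman correlation: ``2*sin(pi*rho_s/6)``."""
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError("Spearman target must lie in [-1, 1]")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass(frozen=True)
class MarginalSpec:
    """Median/IQR-parameterized marginal; family 'lognormal' or 'normal'."""

    median: float
    iqr: float
    family: str = "lognormal"

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise ValueError("family must be 'lognormal' or 'normal'")
        if self.family == "lognormal" and self.median <= 0:
            raise ValueError("lognormal marginal needs a positive median")
        if self.iqr < 0:
            raise ValueError("IQR must be nonnegative")

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        """Monotone transform of standard-normal latents to this marginal."""
        if self.family == "lognormal":
            sigma = np.arcsinh(self.iqr / (2.0 * self.median)) / _Z75
            return self.median * np.exp(sigma * z)
        return self.median + (self.iqr / (2.0 * _Z75)) * z


@dataclass(frozen=True)
class HyperaemiaCurve:
    """Piecewise perfusion time course f(t) in ml/min/100 g.

    Rest plateau at ``baseline``; zero flow during cuff ischemia; at the
    first sampling instant of reperfusion the flow peaks at ``peak`` and
    decays linearly back to baseline over ``decay_s``. Breakpoints sit on
    the 20-s sampling grid so the trapezoidal paradigm summary recovers the
    calibrated total exactly: total = (peak - baseline) * decay / 2.
    """

    baseline: float
    peak: float
    decay_s: float
    paradigm: PhaseTiming = field(default_factory=PhaseTiming)

    def __post_init__(self):
        if self.baseline < 0 or self.peak < self.baseline:
            raise ValueError("need 0 <= baseline <= peak")
        if self.decay_s <= 0:
            raise ValueError("decay time must be positive")

    @property
    def onset_s(self) -> float:
        """First sample time inside the reperfusion phase."""
        start = self.paradigm.rest_s + self.paradigm.ischemia_s
        dt = self.paradigm.map_interval_s
        return float(np.ceil(start / dt) * dt)

    @property
    def total_ml_100g(self) -> float:
        return 0.5 * (self.peak - self.baseline) * self.decay_s / 60.0

    @property
    def maximal_ml_min_100g(self) -> float:
        return self.peak

    def __call__(self, t_s) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        p = self.paradigm
        rest = t < p.rest_s
        isch = (t >= p.rest_s) & (t < p.rest_s + p.ischemia_s)
        overshoot = (self.peak - self.baseline) * np.clip(
            1.0 - (t - self.onset_s) / self.decay_s, 0.0, 1.0
        )
        f = np.where(t >= self.onset_s, self.baseline + overshoot, self.baseline)
        f = np.where(isch, 0.0, f)
        f = np.where(rest, self.baseline, f)
        return f


# ------------------------------------------------------------------ presets


@dataclass(frozen=True)
class GeneratorPreset:
    """Ground-truth parameters of one experimental group.

    Medians/IQRs are the reference pooled-group values; ground-truth scalars
    (preset medians) drive the noiseless single-signal generators, while the
    marginals drive cohort draws.
    """

    name: str
    group: str  # 'injured' | 'control'
    strain: str = "pooled"

    # T1 / ECV (plasma T1 values are shared protocol-level ground truth)
    native_t1_ms: MarginalSpec = field(default_factory=lambda: MarginalSpec(1649.9, 37.6))
    ecv_pct: MarginalSpec = field(default_factory=lambda: MarginalSpec(5.9, 1.4))
    plasma_t1_pre_ms: float = 2200.0
    plasma_t1_post_ms: float = 400.0

    # MSME T2 mapping
    t2_msme_ms: MarginalSpec = field(default_factory=lambda: MarginalSpec(21.5, 0.6))
    b1_scale: float = 0.9

    # ISIS-CPMG spectrum: (fraction, T2 ms) per component
    cpmg_components: tuple = ((0.08, 10.0), (0.80, 40.0), (0.12, 140.0))

    # UTE T2*
    t2star_short_ms: MarginalSpec = field(default_factory=lambda: MarginalSpec(0.63, 0.88))
    t2star_long_ms: MarginalSpec = field(default_factory=lambda: MarginalSpec(17.3, 7.0))
    t2star_short_frac_pct: MarginalSpec = field(default_factory=lambda: MarginalSpec(4.9, 3.5))

    # perfusion (curve calibrated so the paradigm summary hits the medians)
    perfusion_total: MarginalSpec = field(default_factory=lambda: MarginalSpec(50.0, 161.0))
    perfusion_max: MarginalSpec = field(default_factory=lambda: MarginalSpec(80.9, 50.4))
    perfusion_decay_s: float = 80.0

    # SWE
    smi: MarginalSpec = field(default_factory=lambda: MarginalSpec(0.67, 0.44))
    sm0_kpa: MarginalSpec = field(default_factory=lambda: MarginalSpec(6.0, 1.2))

    # texture
    skewness: MarginalSpec = field(default_factory=lambda: MarginalSpec(0.2, 0.5, "normal"))
    kurtosis: MarginalSpec = field(default_factory=lambda: MarginalSpec(3.6, 0.7))
    energy: MarginalSpec = field(default_factory=lambda: MarginalSpec(0.095, 0.025))
    texture_base_mean: float = 100.0
    texture_base_sd: float = 10.0
    texture_outlier_fraction: float = 0.01
    texture_outlier_shift: float = -40.0

    # histology
    collagen_total_pct: MarginalSpec = field(default_factory=lambda: MarginalSpec(12.5, 2.0))
    collagen_endo_pct: MarginalSpec = field(default_factory=lambda: MarginalSpec(10.0, 3.0))
    # ordinal score probabilities for levels 0..3
    score_probs: dict = field(
        default_factory=lambda: {
            "inflammation": (0.9, 0.1, 0.0, 0.0),
            "centronucleation": (0.9, 0.1, 0.0, 0.0),
            "calcification": (1.0, 0.0, 0.0, 0.0),
        }
    )

    #: metric -> (anchor collagen column, target Spearman correlation)
    spearman_targets: dict = field(
        default_factory=lambda: {
            "ecv_pct": ("collagen_total_pct", 0.50),
            "t2_msme_ms": ("collagen_total_pct", -0.48),
            "smi": ("collagen_total_pct", 0.41),
            "sm80_kpa": ("collagen_total_pct", 0.46),
            "kurtosis": ("collagen_endo_pct", 0.42),
            "energy": ("collagen_endo_pct", 0.35),
            "t2star_short_ms": ("collagen_endo_pct", 0.36),
            "perfusion_total_ml_100g": ("collagen_endo_pct", 0.35),
        }
    )
    #: Spearman correlation between total and endomysial collagen fraction
    collagen_cross_spearman: float = 0.92

    def __post_init__(self):
        if self.group not in ("injured", "control"):
            raise ValueError("group must be 'injured' or 'control'")
        fr = sum(f for f, _ in self.cpmg_components)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("CPMG component fractions must sum to 1")
        if not 0 < self.b1_scale <= 1.5:
            raise ValueError("B1 scale must lie in (0, 1.5]")
        for metric, (anchor, rho) in self.spearman_targets.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(
                    f"Spearman target for ({metric}, {anchor}) outside [-1, 1]"
                )

    # -------- derived ground-truth scalars (preset medians)

    @property
    def muscle_t1_post_ms(self) -> float:
        """Post-contrast muscle T1 consistent with the preset ECV median."""
        dr1_p = 1.0 / self.plasma_t1_post_ms - 1.0 / self.plasma_t1_pre_ms
        dr1_m = (self.ecv_pct.median / 100.0) * dr1_p
        return 1.0 / (1.0 / self.native_t1_ms.median + dr1_m)

    @property
    def ute_amplitudes(self) -> tuple[float, float]:
        """(A_short, A_long) for unit total amplitude at TE=0."""
        f = self.t2star_short_frac_pct.median / 100.0
        return f, 1.0 - f

    @property
    def perfusion_baseline(self) -> float:
        """Rest flow making the triangular overshoot integrate to the preset
        total: baseline = peak - 2*total/decay_minutes."""
        b = self.perfusion_max.median - 2.0 * self.perfusion_total.median / (
            self.perfusion_decay_s / 60.0
        )
        if b < 0:
            raise ValueError("perfusion preset infeasible: negative rest baseline")
        return b

    def perfusion_curve(self, paradigm: PhaseTiming | None = None) -> HyperaemiaCurve:
        return HyperaemiaCurve(
            self.perfusion_baseline,
            self.perfusion_max.median,
            self.perfusion_decay_s,
            paradigm or PhaseTiming(),
        )

    @property
    def sm_by_angle_kpa(self) -> dict:
        """Monotone shear-modulus profile consistent with the SMi median."""
        sm0 = self.sm0_kpa.median
        s = self.smi.median
        return {0: sm0, 40: sm0 * (1 + 0.45 * s), 60: sm0 * (1 + 0.75 * s), 80: sm0 * (1 + s)}

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = (v.median, v.iqr, v.family) if isinstance(v, MarginalSpec) else v
        return out


_POOLED_CONTROL = GeneratorPreset(name="pooled_control", group="control")

_POOLED_INJURED = GeneratorPreset(
    name="pooled_injured",
    group="injured",
    native_t1_ms=MarginalSpec(1647.0, 38.6),
    ecv_pct=MarginalSpec(6.6, 2.0),
    t2_msme_ms=MarginalSpec(21.4, 0.8),
    cpmg_components=((0.10, 10.0), (0.75, 40.0), (0.15, 140.0)),
    t2star_short_ms=MarginalSpec(0.51, 0.71),
    t2star_long_ms=MarginalSpec(13.0, 6.6),
    t2star_short_frac_pct=MarginalSpec(5.8, 4.1),
    perfusion_total=MarginalSpec(252.6, 138.6),
    perfusion_max=MarginalSpec(91.5, 37.0),
    perfusion_decay_s=360.0,
    smi=MarginalSpec(1.17, 1.00),
    sm0_kpa=MarginalSpec(6.0, 1.5),
    skewness=MarginalSpec(0.5, 0.6, "normal"),
    kurtosis=MarginalSpec(4.7, 2.8),
    energy=MarginalSpec(0.111, 0.032),
    texture_outlier_fraction=0.06,
    collagen_total_pct=MarginalSpec(17.0, 3.0),
    collagen_endo_pct=MarginalSpec(14.0, 2.0),
    score_probs={
        "inflammation": (0.2, 0.5, 0.3, 0.0),
        "centronucleation": (0.0, 0.3, 0.5, 0.2),
        "calcification": (0.7, 0.25, 0.05, 0.0),
    },
)

# Strain-specific variants differ from the pooled presets only in their
# collagen medians; no other strain-resolved reference values are available.
PRESETS: dict[str, GeneratorPreset] = {
    "pooled_control": _POOLED_CONTROL,
    "pooled_injured": _POOLED_INJURED,
    "dba2j_injured": replace(
        _POOLED_INJURED,
        name="dba2j_injured",
        strain="DBA/2J",
        collagen_total_pct=MarginalSpec(18.0, 3.0),
        collagen_endo_pct=MarginalSpec(14.0, 2.5),
    ),
    "dba2j_control": replace(
        _POOLED_CONTROL,
        name="dba2j_control",
        strain="DBA/2J",
        collagen_total_pct=MarginalSpec(13.0, 3.0),
        collagen_endo_pct=MarginalSpec(10.0, 2.0),
    ),
    "c57bl6_injured": replace(
        _POOLED_INJURED,
        name="c57bl6_injured",
        strain="C57BL/6",
        collagen_total_pct=MarginalSpec(15.0, 2.5),
        collagen_endo_pct=MarginalSpec(12.0, 2.0),
    ),
    "c57bl6_control": replace(
        _POOLED_CONTROL,
        name="c57bl6_control",
        strain="C57BL/6",
        collagen_total_pct=MarginalSpec(11.0, 2.5),
        collagen_endo_pct=MarginalSpec(9.0, 2.5),
    ),
}


def get_preset(name: str) -> GeneratorPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# --------------------------------------------------------- signal generators


def gen_t1_series(
    t1_ms: float,
    trs_ms=T1_SR_TR_MS,
    scale: float = 1.0,
    efficiency: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RelaxationSignal:
    """Saturation-recovery series S(TR) = scale*(1 - eff*exp(-TR/T1)) + noise."""
    tr = np.sort(np.asarray(trs_ms, dtype=float))
    if tr.size == 0 or np.any(tr <= 0):
        raise ValueError("TR list must be nonempty and positive")
    if t1_ms <= 0:
        raise ValueError("T1 must be positive")
    s = scale * (1.0 - efficiency * np.exp(-tr / t1_ms))
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0.0, noise_sd, tr.size)
    return RelaxationSignal(tr, s, "T1SR")


def gen_cpmg_signal(
    components,
    esp_ms: float = CPMG_ESP_MS,
    n_echoes: int = CPMG_N_ECHOES,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
) -> RelaxationSignal:
    """Multi-exponential CPMG decay sampled at k*esp, k = 1..n_echoes.

    ``components`` is a sequence of (fraction, T2 ms); fractions must sum
    to 1 (tolerance 1e-6) and T2 values must be positive.
    """
    comps = [(float(f), float(t2)) for f, t2 in components]
    if abs(sum(f for f, _ in comps) - 1.0) > 1e-6:
        raise ValueError("component fractions must sum to 1")
    if any(t2 <= 0 for _, t2 in comps):
        raise ValueError("T2 values must be positive")
    t = esp_ms * np.arange(1, n_echoes + 1)
    s = scale * sum(f * np.exp(-t / t2) for f, t2 in comps)
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return RelaxationSignal(t, s, "CPMG")


def gen_ute_signal(
    a_short: float,
    a_long: float,
    t2star_short_ms: float,
    t2star_long_ms: float,
    tes_ms=UTE_TE_MS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RelaxationSignal:
    """Magnitude of the oscillatory bi-exponential UTE model plus noise.

    The short component oscillates at the fixed 970 Hz chemical shift.
    """
    te = np.asarray(tes_ms, dtype=float)
    if te.size == 0:
        raise ValueError("TE list must be nonempty")
    if a_short < 0 or a_long < 0:
        raise ValueError("amplitudes must be nonnegative")
    if t2star_short_ms <= 0 or t2star_long_ms <= 0:
        raise ValueError("T2* values must be positive")
    s = ute_model_amplitude(te, "biexp_osc", (a_short, a_long, t2star_short_ms, t2star_long_ms))
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0.0, noise_sd, te.size)
    return RelaxationSignal(te, s, "UTE")


def gen_asl_series(
    perfusion_curve,
    paradigm: PhaseTiming | None = None,
    constants: PerfusionConstants | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    m0: float = 1.0,
) -> ASLSeries:
    """Tagged/control pairs whose relative difference inverts to the curve.

    The forward model is the exact inverse of the quantification equation,
    so a noiseless series round-trips bit-exactly. The curve must be
    nonnegative, zero during ischemia, and below the model singularity.
    """
    paradigm = paradigm or PhaseTiming()
    constants = constants or PerfusionConstants()
    t = paradigm.sample_times()
    f = np.asarray(perfusion_curve(t), dtype=float)
    if np.any(f < 0):
        raise ValueError("perfusion curve must be nonnegative")
    phases = paradigm.phase_of(t)
    if np.any(f[phases == "ischemia"] != 0):
        raise ValueError("perfusion curve must be zero during ischemia")
    r = perfusion_forward_ratio(f, constants)
    if np.any(r >= constants.inflow_efficiency):
        raise ValueError("curve reaches the quantification singularity (r >= exp(-tT/T1a))")
    control = np.full(t.size, m0)
    tagged = control * (1.0 - r)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        control = control + rng.normal(0.0, noise_sd, t.size)
        tagged = tagged + rng.normal(0.0, noise_sd, t.size)
    return ASLSeries(t, control, tagged, phases)


def gen_swe_profile(sm_by_angle_kpa: dict, noise_sd: float = 0.0, seed: int = 0) -> SWEMeasurement:
    """Per-angle shear-modulus readings with optional Gaussian noise."""
    missing = [a for a in SWE_ANGLES_DEG if a not in sm_by_angle_kpa]
    if missing:
        raise ValueError(f"missing angle(s) {missing}")
    rng = np.random.default_rng(seed)
    out = {}
    for a in sorted(sm_by_angle_kpa):
        v = float(sm_by_angle_kpa[a])
        if noise_sd > 0:
            v = max(v + rng.normal(0.0, noise_sd), 1e-6)
        out[a] = v
    return SWEMeasurement(out)


def gen_texture_roi(
    n_pixels: int,
    base_mean: float = 100.0,
    base_sd: float = 10.0,
    outlier_fraction: float = 0.0,
    outlier_shift: float = -40.0,
    quant_levels: int = 256,
    seed: int = 0,
) -> np.ndarray:
    """Quantized Gaussian-mixture ROI intensity sample.

    A fraction of pixels is drawn from a component shifted by
    ``outlier_shift`` (same sd), emulating the intensity outliers that raise
    kurtosis in fibrotic muscle; the sample is then uniformly quantized to
    ``quant_levels`` level centers.
    """
    if not 0 <= outlier_fraction < 0.5:
        raise ValueError("outlier fraction must lie in [0, 0.5)")
    if quant_levels < 2:
        raise ValueError("need at least 2 quantization levels")
    if n_pixels < 1:
        raise ValueError("need at least one pixel")
    rng = np.random.default_rng(seed)
    is_out = rng.random(n_pixels) < outlier_fraction
    x = base_mean + rng.normal(0.0, 1.0, n_pixels) * base_sd + np.where(is_out, outlier_shift, 0.0)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full(n_pixels, lo)
    codes = np.clip(np.floor((x - lo) / (hi - lo) * quant_levels), 0, quant_levels - 1)
    width = (hi - lo) / quant_levels
    return lo + (codes + 0.5) * width


def texture_roi_image(shape: tuple, seed: int = 0, **kwargs) -> np.ndarray:
    """2-D arrangement of a generated ROI sample (row-major); for I/O tests
    only -- histogram features ignore spatial structure."""
    n = int(np.prod(shape))
    return gen_texture_roi(n, seed=seed, **kwargs).reshape(shape)


# ------------------------------------------------------------------- cohort


@dataclass(frozen=True)
class SyntheticCohort:
    """Paired synthetic cohort: one injured and one control muscle per animal."""

    table: pd.DataFrame
    seed: int
    preset_names: tuple[str, str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_COHORT_METRICS = (
    # column, marginal attribute
    ("ecv_pct", "ecv_pct"),
    ("native_t1_ms", "native_t1_ms"),
    ("t2_msme_ms", "t2_msme_ms"),
    ("t2star_short_ms", "t2star_short_ms"),
    ("t2star_long_ms", "t2star_long_ms"),
    ("t2star_short_frac_pct", "t2star_short_frac_pct"),
    ("perfusion_total_ml_100g", "perfusion_total"),
    ("perfusion_max_ml_min_100g", "perfusion_max"),
    ("smi", "smi"),
    ("sm0_kpa", "sm0_kpa"),
    ("skewness", "skewness"),
    ("kurtosis", "kurtosis"),
    ("energy", "energy"),
)


def _draw_group(preset: GeneratorPreset, n: int, rng, correlation_targets) -> pd.DataFrame:
    """Draw n muscle records for one group via the latent-factor copula."""
    z_total = rng.standard_normal(n)
    rho_c = spearman_to_latent(preset.collagen_cross_spearman)
    z_endo = rho_c * z_total + np.sqrt(1 - rho_c**2) * rng.standard_normal(n)
    anchors = {"collagen_total_pct": z_total, "collagen_endo_pct": z_endo}

    rec: dict[str, np.ndarray] = {}
    rec["collagen_total_pct"] = preset.collagen_total_pct.from_latent(z_total)
    rec["collagen_endo_pct"] = preset.collagen_endo_pct.from_latent(z_endo)

    for col, attr in _COHORT_METRICS:
        marg: MarginalSpec = getattr(preset, attr)
        if col in correlation_targets:
            anchor_name, rho_s = correlation_targets[col]
            if anchor_name not in anchors:
                raise ValueError(
                    f"correlation target for ({col}, {anchor_name}): unknown anchor"
                )
            if not -1.0 <= rho_s <= 1.0:
                raise ValueError(
                    f"infeasible correlation target for ({col}, {anchor_name}): "
                    f"{rho_s} outside [-1, 1]"
                )
            a = spearman_to_latent(rho_s)
            z = a * anchors[anchor_name] + np.sqrt(1 - a**2) * rng.standard_normal(n)
        else:
            z = rng.standard_normal(n)
        rec[col] = marg.from_latent(z)

    # SM80 derived so the SMi identity holds exactly per record
    rec["sm80_kpa"] = rec["sm0_kpa"] * (1.0 + rec["smi"])

    # CPMG spectrum: components jittered around the preset, fractions renormalized
    fracs = np.array([f for f, _ in preset.cpmg_components])
    t2s = np.array([t2 for _, t2 in preset.cpmg_components])
    w = fracs[None, :] * np.exp(rng.normal(0.0, 0.10, (n, 3)))
    w /= w.sum(axis=1, keepdims=True)
    tt = t2s[None, :] * np.exp(rng.normal(0.0, 0.05, (n, 3)))
    for i, suffix in enumerate(("s", "i", "l")):
        rec[f"cpmg_t2{suffix}_ms"] = tt[:, i]
        rec[f"cpmg_frac_{suffix}"] = w[:, i]

    for score, probs in preset.score_probs.items():
        p = np.asarray(probs, dtype=float)
        rec[f"{score}_score"] = rng.choice(4, size=n, p=p / p.sum())

    df = pd.DataFrame(rec)
    df.insert(0, "group", preset.group)
    df.insert(0, "side", "left" if preset.group == "injured" else "right")
    df.insert(0, "strain", preset.strain)
    return df


def gen_cohort(
    preset_pair=("pooled_injured", "pooled_control"),
    n_animals: int = 18,
    correlation_targets: dict | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a paired injured/control cohort table.

    Parameters
    ----------
    preset_pair
        (injured, control) preset names or :class:`GeneratorPreset` objects.
    n_animals
        Number of animals (>= 3); each contributes two muscle rows.
    correlation_targets
        Optional override of the injured preset's
        ``{metric: (collagen column, Spearman target)}`` map, applied to both
        groups.
    seed
        Any source of randomness; regeneration with the same seed is
        bit-identical.
    """
    if n_animals < 3:
        raise ValueError("need at least 3 animals")
    inj, ctl = (get_preset(p) if isinstance(p, str) else p for p in preset_pair)
    if inj.group != "injured" or ctl.group != "control":
        raise ValueError("preset_pair must be (injured, control)")
    rng = np.random.default_rng(seed)
    targets = dict(inj.spearman_targets if correlation_targets is None else correlation_targets)

    df_i = _draw_group(inj, n_animals, rng, targets)
    df_c = _draw_group(ctl, n_animals, rng, targets)
    for df in (df_i, df_c):
        df.insert(0, "animal_id", [f"M{k:04d}" for k in range(n_animals)])
    table = (
        pd.concat([df_i, df_c], ignore_index=True)
        .sort_values(["animal_id", "group"], kind="stable")
        .reset_index(drop=True)
    )
    return SyntheticCohort(table, seed, (inj.name, ctl.name))
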