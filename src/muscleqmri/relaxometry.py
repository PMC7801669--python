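"""Nonlinear least-squares estimation of T1, ECV, multi-component CPMG T2
spectra and UTE T2* components, with F-test model-order selection.

Models
------
Saturation recovery (T1 mapping)
    ``S(TR) = M0 * (1 - eff * exp(-TR/T1))``, where the free efficiency
    ``eff`` absorbs imperfect saturation and surface-coil flip-angle
    variation.
ECV
    Ratio of gadolinium-induced relaxation-rate changes
    ``ECV = (R1_post - R1_pre)_muscle / (R1_post - R1_pre)_plasma``.
CPMG T2 spectrum
    Discrete 1-, 2- or 3-component exponential decay; components reported
    sorted by T2 with amplitude fractions normalized to 1.
UTE T2*
    Mono-exponential; bi-exponential; or bi-exponential with the short
    component oscillating at a fixed 970 Hz chemical shift, fitted as the
    magnitude of the complex model to the amplitude decay.

Competing nested models are compared with an F-test on residual sums of
squares; the more complex model is retained when its p-value clears alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .signals import RelaxationSignal, UTE_CHEMICAL_SHIFT_HZ

__all__ = [
    "T1Fit",
    "ECVResult",
    "MultiExpFit",
    "UTEFit",
    "ModelChoice",
    "fit_t1",
    "compute_ecv",
    "compute_ecv_map",
    "fit_multiexponential",
    "fit_ute",
    "ftest_select",
]


# --------------------------------------------------------------------------- T1


@dataclass(frozen=True)
class T1Fit:
    """Saturation-recovery fit: T1 (ms), scale M0, saturation efficiency, RSS."""

    t1_ms: float
    m0: float
    efficiency: float
    rss: float
    converged: bool = True

    def __post_init__(self):
        if self.converged and self.t1_ms <= 0:
            raise ValueError("T1 must be positive")


def _sr_model(tr, m0, eff, t1):
    return m0 * (1.0 - eff * np.exp(-tr / t1))


def fit_t1(signal: RelaxationSignal) -> T1Fit:
    """Fit ``S(TR) = M0*(1 - eff*exp(-TR/T1))`` by bounded least squares.

    Requires at least 4 samples (3 free parameters). Initialization uses the
    longest-TR amplitude for M0 and a coarse T1 grid; additional restarts
    guard against local minima. Non-convergence is flagged rather than raised.
    """
    tr = signal.times_ms
    s = signal.amplitudes
    if tr.size < 4:
        raise ValueError("fit_t1 requires at least 4 samples")
    m0_init = max(float(s[-1]), 1e-12)
    starts = [(m0_init, 1.0, t1g) for t1g in (200.0, 800.0, 1650.0, 3000.0)]
    lb = [0.0, 1e-6, 1e-3]
    ub = [np.inf, 2.0, 1e7]
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _sr_model, tr, s, p0=p0, bounds=(lb, ub), maxfev=20000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_sr_model(tr, *popt) - s) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return T1Fit(np.nan, np.nan, np.nan, np.nan, converged=False)
    (m0, eff, t1), rss = best
    return T1Fit(float(t1), float(m0), float(eff), rss)


# -------------------------------------------------------------------------- ECV


@dataclass(frozen=True)
class ECVResult:
    """Extracellular volume fraction with the R1 changes that produced it."""

    ecv: float
    delta_r1_muscle: float  # 1/ms
    delta_r1_plasma: float  # 1/ms

    @property
    def ecv_percent(self) -> float:
        return 100.0 * self.ecv


def compute_ecv(
    muscle_t1_pre_ms: float,
    muscle_t1_post_ms: float,
    plasma_t1_pre_ms: float,
    plasma_t1_post_ms: float,
) -> ECVResult:
    """ECV as the ratio of muscle to plasma gadolinium-induced R1 change.

    The plasma R1 must increase after contrast (post-T1 < pre-T1); otherwise
    no contrast arrived and the ratio is undefined.
    """
    for name, t1 in (
        ("muscle pre", muscle_t1_pre_ms),
        ("muscle post", muscle_t1_post_ms),
        ("plasma pre", plasma_t1_pre_ms),
        ("plasma post", plasma_t1_post_ms),
    ):
        if not np.isfinite(t1) or t1 <= 0:
            raise ValueError(f"{name} T1 must be positive and finite")
    dr1_p = 1.0 / plasma_t1_post_ms - 1.0 / plasma_t1_pre_ms
    if dr1_p <= 0:
        raise ValueError("plasma R1 change must be positive (no contrast arrived)")
    dr1_m = 1.0 / muscle_t1_post_ms - 1.0 / muscle_t1_pre_ms
    return ECVResult(dr1_m / dr1_p, dr1_m, dr1_p)


def compute_ecv_map(
    muscle_t1_pre_map,
    muscle_t1_post_map,
    plasma_t1_pre_ms: float,
    plasma_t1_post_ms: float,
) -> np.ndarray:
    """Voxelwise ECV from pre/post T1 maps and scalar plasma T1 values.

    Non-finite or nonpositive voxels propagate as NaN.
    """
    pre = np.asarray(muscle_t1_pre_map, dtype=float)
    post = np.asarray(muscle_t1_post_map, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post maps must share a shape")
    dr1_p = 1.0 / plasma_t1_post_ms - 1.0 / plasma_t1_pre_ms
    if dr1_p <= 0:
        raise ValueError("plasma R1 change must be positive (no contrast arrived)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ecv = (1.0 / post - 1.0 / pre) / dr1_p
    bad = ~np.isfinite(pre) | ~np.isfinite(post) | (pre <= 0) | (post <= 0)
    ecv[bad] = np.nan
    return ecv


# ----------------------------------------------------------- CPMG multi-exp


@dataclass(frozen=True)
class MultiExpFit:
    """Discrete multi-exponential T2 fit, components sorted ascending by T2."""

    order: int
    amplitudes: tuple[float, ...]
    t2_ms: tuple[float, ...]
    rss: float
    n_samples: int
    converged: bool = True

    @property
    def n_params(self) -> int:
        return 2 * self.order

    @property
    def dof(self) -> int:
        return self.n_samples - self.n_params

    @property
    def fractions(self) -> tuple[float, ...]:
        total = sum(self.amplitudes)
        if total <= 0:
            return tuple(np.nan for _ in self.amplitudes)
        return tuple(a / total for a in self.amplitudes)


def _multiexp_model(t, params):
    order = len(params) // 2
    amps = params[:order]
    t2s = params[order:]
    return sum(a * np.exp(-t / T) for a, T in zip(amps, t2s))


def _log_tail_estimate(t, s, tail_frac=0.3):
    """Log-linear estimate of the slowest component from the decay tail."""
    n = max(3, int(round(tail_frac * t.size)))
    tt, ss = t[-n:], s[-n:]
    pos = ss > 0
    if pos.sum() < 3:
        return float(s[0]), float(t[-1] / 3.0)
    slope, intercept = np.polyfit(tt[pos], np.log(ss[pos]), 1)
    if slope >= 0:
        return float(s[0]), float(t[-1] / 3.0)
    return float(np.exp(intercept)), float(-1.0 / slope)


def _multiexp_starts(t, s, order, rng):
    """Initial parameter sets: residual peeling plus jittered restarts."""
    # peel from slowest to fastest
    amps, t2s = [], []
    resid = s.copy()
    tt = t.copy()
    for _ in range(order):
        a, T = _log_tail_estimate(tt, np.clip(resid, 0, None))
        amps.append(max(a, 1e-9))
        t2s.append(max(T, 1e-3))
        resid = resid - a * np.exp(-tt / T)
        # subsequent components live at earlier times
        keep = max(4, tt.size // 2)
        tt = tt[:keep]
        resid = resid[:keep]
    base = np.array(amps + t2s)
    starts = [base]
    # geometric spread of T2 guesses as a fallback
    span = np.geomspace(t[0] if t[0] > 0 else t[1] / 2, t[-1], order + 2)[1:-1]
    alt = np.concatenate([np.full(order, max(s[0] / order, 1e-9)), span])
    starts.append(alt)
    for _ in range(6):
        jit = base * np.exp(rng.normal(0, 0.4, base.size))
        starts.append(jit)
    return starts


def fit_multiexponential(
    signal: RelaxationSignal, order: int, seed: int = 0
) -> MultiExpFit:
    """Bounded nonlinear least-squares fit of a 1-, 2- or 3-exponential decay.

    Amplitudes constrained nonnegative; returned components sorted ascending
    by T2. Multi-start initialization: log-linear tail estimate plus residual
    peeling, then jittered restarts, keeping the lowest-RSS solution.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    t = signal.times_ms
    s = signal.amplitudes
    if t.size < 2 * order + 1:
        raise ValueError(f"order-{order} fit needs >= {2 * order + 1} samples")
    rng = np.random.default_rng(seed)

    lb = np.concatenate([np.zeros(order), np.full(order, 1e-4)])
    ub = np.concatenate([np.full(order, np.inf), np.full(order, 1e6)])

    def resid_fn(p):
        return _multiexp_model(t, p) - s

    best = None
    for p0 in _multiexp_starts(t, s, order, rng):
        p0 = np.clip(p0, lb + 1e-12, None)
        try:
            res = optimize.least_squares(resid_fn, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        return MultiExpFit(order, (np.nan,) * order, (np.nan,) * order, np.nan, t.size, converged=False)
    p, rss = best
    amps, t2s = p[:order], p[order:]
    idx = np.argsort(t2s)
    return MultiExpFit(order, tuple(amps[idx]), tuple(t2s[idx]), rss, t.size)


# --------------------------------------------------------------------- UTE T2*

UTE_MODELS = ("mono", "biexp", "biexp_osc")


@dataclass(frozen=True)
class UTEFit:
    """UTE T2* fit. For bi-exponential models ``amplitudes=(A_short, A_long)``
    and ``t2star_ms=(short, long)``; the oscillation frequency is fixed."""

    model: str
    amplitudes: tuple[float, ...]
    t2star_ms: tuple[float, ...]
    rss: float
    n_samples: int
    frequency_hz: float = UTE_CHEMICAL_SHIFT_HZ
    converged: bool = True

    @property
    def n_params(self) -> int:
        return 2 * len(self.amplitudes)

    @property
    def dof(self) -> int:
        return self.n_samples - self.n_params

    @property
    def short_fraction(self) -> float:
        """A_short/(A_short+A_long) at TE=0; NaN for the mono model."""
        if len(self.amplitudes) < 2:
            return np.nan
        a_s, a_l = self.amplitudes
        return a_s / (a_s + a_l) if (a_s + a_l) > 0 else np.nan


def ute_model_amplitude(te_ms, model, params, frequency_hz=UTE_CHEMICAL_SHIFT_HZ):
    """Magnitude of the UTE signal model at the given echo times (ms)."""
    te = np.asarray(te_ms, dtype=float)
    if model == "mono":
        a0, t2 = params
        return a0 * np.exp(-te / t2)
    a_s, a_l, t2s, t2l = params
    long_part = a_l * np.exp(-te / t2l)
    if model == "biexp":
        return a_s * np.exp(-te / t2s) + long_part
    if model == "biexp_osc":
        # 970 Hz = frequency_hz/1000 cycles per ms
        phase = 2j * np.pi * (frequency_hz / 1000.0) * te
        short_part = a_s * np.exp((-1.0 / t2s) * te + phase)
        return np.abs(short_part + long_part)
    raise ValueError(f"unknown UTE model {model!r}")


def fit_ute(signal: RelaxationSignal, model: str = "biexp_osc", seed: int = 0) -> UTEFit:
    """Fit a UTE amplitude decay to the mono/biexp/oscillatory-biexp model.

    The 970 Hz chemical-shift frequency of the short component is fixed, not
    fitted. Amplitudes are constrained nonnegative and the short T2* is kept
    below the long one by construction of the starts and a post-fit sort.
    """
    if model not in UTE_MODELS:
        raise ValueError(f"model must be one of {UTE_MODELS}")
    te = signal.times_ms
    s = signal.amplitudes
    min_n = 3 if model == "mono" else 6
    if te.size < min_n:
        raise ValueError(f"{model} fit needs >= {min_n} samples")
    rng = np.random.default_rng(seed)

    a0_est, t2l_est = _log_tail_estimate(te, np.clip(s, 0, None), tail_frac=0.4)
    a0_est = max(a0_est, 1e-9)
    t2l_est = float(np.clip(t2l_est, 0.5, 1e3))

    if model == "mono":
        lb, ub = [0.0, 1e-4], [np.inf, 1e5]
        starts = [np.array([a0_est, t2l_est]), np.array([max(s[0], 1e-9), te[-1] / 2])]
    else:
        a_s0 = max(float(s[0]) - a0_est, 1e-3 * a0_est)
        lb = [0.0, 0.0, 1e-4, 1e-4]
        ub = [np.inf, np.inf, 1e5, 1e5]
        starts = [np.array([a_s0, a0_est, 0.5, t2l_est])]
        for t2s0 in (0.2, 1.0):
            starts.append(np.array([a_s0, a0_est, t2s0, t2l_est]))
        for _ in range(5):
            jit = starts[0] * np.exp(rng.normal(0, 0.4, 4))
            starts.append(jit)

    def resid_fn(p):
        return ute_model_amplitude(te, model, p) - s

    best = None
    for p0 in starts:
        p0 = np.clip(p0, np.asarray(lb) + 1e-12, None)
        try:
            res = optimize.least_squares(resid_fn, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        n_a = 1 if model == "mono" else 2
        return UTEFit(model, (np.nan,) * n_a, (np.nan,) * n_a, np.nan, te.size, converged=False)
    p, rss = best
    if model == "mono":
        return UTEFit(model, (float(p[0]),), (float(p[1]),), rss, te.size)
    a_s, a_l, t2s, t2l = p
    if t2s > t2l:  # keep short < long
        a_s, a_l, t2s, t2l = a_l, a_s, t2l, t2s
    return UTEFit(model, (float(a_s), float(a_l)), (float(t2s), float(t2l)), rss, te.size)


# ---------------------------------------------------------- F-test selection


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of sequential F-tests between nested fits."""

    chosen: str
    f_statistics: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)


def _fit_id(fit) -> str:
    if isinstance(fit, MultiExpFit):
        return f"order{fit.order}"
    return fit.model


def ftest_select(fits, alpha: float = 0.05) -> ModelChoice:
    """Select among nested fits by sequential F-tests, simple to complex.

    ``F = ((RSS_s - RSS_c)/dp) / (RSS_c/(n - p_c))``; the complex model is
    retained when p < alpha. Fits must be on the same data (equal sample
    count) and are ordered by parameter count; a zero complex RSS yields an
    infinite F (complex model accepted, flagged).
    """
    fits = sorted(fits, key=lambda f: f.n_params)
    if len(fits) < 2:
        raise ValueError("need at least two nested fits")
    n = fits[0].n_samples
    if any(f.n_samples != n for f in fits):
        raise ValueError("fits must be computed on the same data")
    chosen = fits[0]
    f_stats, p_vals = {}, {}
    for cand in fits[1:]:
        dp = cand.n_params - chosen.n_params
        if dp <= 0:
            # equal parameter count: keep the lower-RSS fit (higher F vs the
            # last accepted simpler model)
            if cand.rss < chosen.rss:
                chosen = cand
            continue
        dof_c = n - cand.n_params
        if dof_c <= 0:
            continue
        key = f"{_fit_id(chosen)}->{_fit_id(cand)}"
        if cand.rss <= 0:
            f_stats[key], p_vals[key] = np.inf, 0.0
            chosen = cand
            continue
        f = max((chosen.rss - cand.rss) / dp / (cand.rss / dof_c), 0.0)
        p = float(stats.f.sf(f, dp, dof_c))
        f_stats[key], p_vals[key] = float(f), p
        if p < alpha:
            chosen = cand
    return ModelChoice(_fit_id(chosen), f_stats, p_vals)
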