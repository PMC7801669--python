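"""Paired nonparametric comparisons, rank correlations with covariates,
fibrosis classification and ROC analysis including unweighted composite
indices.

The cohort design is paired: each animal contributes one injured and one
control muscle. Group comparisons use the paired Wilcoxon signed-rank test
(exact null for small n) with Bonferroni correction across the metric
family. Associations between imaging metrics and histological collagen
fraction use Spearman rank correlations; partial Spearman correlations
residualize mid-ranks on covariate mid-ranks (ordinal histology scores and
perfusion metrics) before the Pearson step, with df = n - 2 - k.

Fibrotic classification uses a total-collagen threshold (default 14%:
fibrotic iff collagen > 14%). ROC AUC is the Mann-Whitney pair-counting
statistic with half credit for ties; its 95% CI comes from the DeLong
variance estimate. The composite index robust-standardizes each metric
(median/IQR), orients its sign so the univariate AUC is >= 0.5, and averages
the signed standardized metrics with equal weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "CompositeIndexResult",
    "paired_wilcoxon",
    "kruskal_wallis",
    "spearman",
    "partial_spearman",
    "classify_fibrosis",
    "roc_auc",
    "delong_ci",
    "composed_index",
    "incremental_panel",
]


def _complete(*cols):
    arrs = [np.asarray(c, dtype=float) for c in cols]
    ok = np.all(np.isfinite(np.column_stack(arrs)), axis=1)
    return [a[ok] for a in arrs]


# ------------------------------------------------------------- comparisons


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    p_adjusted: float
    n: int
    effect: dict = field(default_factory=dict)


def _median_iqr(x):
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q75 - q25)


def paired_wilcoxon(injured, control, m_tests: int = 1) -> TestResult:
    """Paired Wilcoxon signed-rank test on within-animal differences.

    Zero differences are discarded (classic convention); the null is exact
    for n <= 25 usable pairs, otherwise the tie-corrected normal
    approximation is used. Two-sided p, Bonferroni-adjusted over ``m_tests``.
    Reports per-group and delta median (IQR) as the effect summary.
    """
    inj, ctl = _complete(injured, control)
    if inj.size < 3:
        raise ValueError("need >= 3 complete pairs")
    delta = inj - ctl
    nz = delta[delta != 0]
    effect = {
        "injured_median_iqr": _median_iqr(inj),
        "control_median_iqr": _median_iqr(ctl),
        "delta_median_iqr": _median_iqr(delta),
    }
    if nz.size < 3:
        return TestResult(float("nan"), float("nan"), float("nan"), int(nz.size), effect)
    mode = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided", method=mode)
    p_adj = min(1.0, m_tests * float(res.pvalue))
    return TestResult(float(res.statistic), float(res.pvalue), p_adj, int(nz.size), effect)


def kruskal_wallis(*groups, m_tests: int = 1) -> TestResult:
    """Kruskal-Wallis H test with tie correction across >= 2 groups."""
    clean = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        a = a[np.isfinite(a)]
        if a.size < 2:
            raise ValueError("every group needs >= 2 finite values")
        clean.append(a)
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    h, p = sps.kruskal(*clean)
    n = sum(a.size for a in clean)
    return TestResult(float(h), float(p), min(1.0, m_tests * float(p)), n)


# ------------------------------------------------------------- correlations


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    n_covariates: int = 0


def _midranks(x):
    return sps.rankdata(x, method="average")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks, t-approximation p."""
    xa, ya = _complete(x, y)
    n = xa.size
    if n < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("constant input has no rank correlation")
    r = float(np.corrcoef(_midranks(xa), _midranks(ya))[0, 1])
    r_cl = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_cl * np.sqrt((n - 2) / (1.0 - r_cl**2))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n)


def partial_spearman(x, y, covariates=None) -> CorrelationResult:
    """Partial Spearman correlation of x and y given covariate columns.

    All columns (including ordinal scores) are mid-rank transformed; the
    ranks of x and y are residualized on an intercept plus the covariate
    ranks by ordinary least squares, and the Pearson correlation of the
    residuals is tested with df = n - 2 - k. With no covariates this reduces
    exactly to :func:`spearman` (identical r; p from the same t form).
    """
    if covariates is None:
        cov_cols = []
    else:
        arr = np.asarray(covariates, dtype=float)
        cov_cols = [arr] if arr.ndim == 1 else [np.asarray(c) for c in arr]
    cols = _complete(x, y, *cov_cols)
    xa, ya, cov = cols[0], cols[1], cols[2:]
    k = len(cov)
    n = xa.size
    if n < k + 4:
        raise ValueError(f"need >= {k + 4} complete rows for {k} covariate(s)")
    rx, ry = _midranks(xa), _midranks(ya)
    if k == 0:
        r = float(np.corrcoef(rx, ry)[0, 1])
    else:
        Z = np.column_stack([np.ones(n)] + [_midranks(c) for c in cov])
        rank = np.linalg.matrix_rank(Z)
        if rank < Z.shape[1]:
            raise ValueError("collinear covariates: rank-deficient design (check covariate columns)")
        proj = Z @ np.linalg.lstsq(Z, np.column_stack([rx, ry]), rcond=None)[0]
        ex = rx - proj[:, 0]
        ey = ry - proj[:, 1]
        scale = np.sqrt(np.mean(rx**2))
        if np.std(ex) <= 1e-12 * scale or np.std(ey) <= 1e-12 * scale:
            # a variable entirely explained by the covariates has no
            # remaining rank variation: the partial correlation is zero
            return CorrelationResult(0.0, 1.0, n, k)
        r = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - k
    r_cl = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_cl * np.sqrt(df / (1.0 - r_cl**2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r, p, n, k)


# ---------------------------------------------------------------- ROC / AUC

FIBROSIS_THRESHOLD_PCT = 14.0


def classify_fibrosis(collagen_total_pct, threshold_pct: float = FIBROSIS_THRESHOLD_PCT):
    """Label muscles fibrotic iff total collagen fraction exceeds the threshold.

    The default 14% threshold separates normal (<= 14%) from fibrotic
    samples. Accepts scalars or arrays; returns 'normal'/'fibrotic' labels.
    """
    c = np.asarray(collagen_total_pct, dtype=float)
    if np.any((c < 0) | (c > 100)):
        raise ValueError("collagen fraction must lie in [0, 100] percent")
    labels = np.where(c > threshold_pct, "fibrotic", "normal")
    if np.isscalar(collagen_total_pct):
        return str(labels)
    return labels


def _auc_mann_whitney(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # midrank formulation (ties get half credit)
    r = _midranks(np.concatenate([pos, neg]))
    auc = (r[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    return float(auc), pos, neg


def delong_ci(scores, labels, level: float = 0.95):
    """AUC with DeLong variance-based confidence interval, clipped to [0, 1]."""
    auc, pos, neg = _auc_mann_whitney(scores, labels)
    m, n = pos.size, neg.size
    # structural components
    v10 = np.empty(m)
    for i, p in enumerate(pos):
        v10[i] = (np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
    v01 = np.empty(n)
    for j, q in enumerate(neg):
        v01[j] = (np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def roc_auc(scores, labels, level: float = 0.95):
    """ROC AUC (Mann-Whitney with tie handling) and DeLong 95% CI.

    ``labels`` may be booleans or 'fibrotic'/'normal' strings (fibrotic =
    positive class).
    """
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = y == "fibrotic"
    return delong_ci(scores, y, level)


# ---------------------------------------------------------- composite index


@dataclass(frozen=True)
class CompositeIndexResult:
    metrics: tuple[str, ...]
    signs: dict
    index_scores: np.ndarray
    auc: float
    ci: tuple[float, float]


def _robust_standardize(x):
    med = np.nanmedian(x)
    q25, q75 = np.nanpercentile(x, [25, 75])
    iqr = q75 - q25
    if iqr == 0:
        return None
    return (x - med) / iqr


def composed_index(metric_table: pd.DataFrame, panel, labels) -> CompositeIndexResult:
    """Equal-weight signed composite of robust-standardized metrics.

    Each metric is centered on its median and scaled by its IQR across all
    samples; its sign is chosen so the univariate AUC for the fibrotic class
    is >= 0.5 (a metric that decreases with fibrosis contributes negatively).
    The index is the mean of the signed standardized metrics over the
    deduplicated panel; zero-IQR metrics are excluded with a warning.
    """
    import warnings

    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = y == "fibrotic"
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be present")
    panel = list(dict.fromkeys(panel))  # dedupe, keep order
    missing = [m for m in panel if m not in metric_table.columns]
    if missing:
        raise ValueError(f"panel metric(s) not in table: {missing}")

    signs: dict[str, int] = {}
    parts = []
    kept = []
    for name in panel:
        x = metric_table[name].to_numpy(dtype=float)
        z = _robust_standardize(x)
        if z is None:
            warnings.warn(f"metric {name!r} has zero IQR; excluded", RuntimeWarning, stacklevel=2)
            continue
        auc_m, _ = delong_ci(x, y)
        sign = 1 if auc_m >= 0.5 else -1
        signs[name] = sign
        parts.append(sign * z)
        kept.append(name)
    if not parts:
        raise ValueError("no usable metric in panel")
    index = np.nanmean(np.column_stack(parts), axis=1)
    auc, ci = delong_ci(index, y)
    return CompositeIndexResult(tuple(kept), signs, index, auc, ci)


def incremental_panel(metric_table: pd.DataFrame, ordered_metrics, labels):
    """Composite-index AUC trajectory over each prefix of a metric ordering."""
    ordered_metrics = list(ordered_metrics)
    if len(ordered_metrics) < 2:
        raise ValueError("need at least two metrics for an incremental panel")
    return [
        composed_index(metric_table, ordered_metrics[: k + 1], labels)
        for k in range(len(ordered_metrics))
    ]
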