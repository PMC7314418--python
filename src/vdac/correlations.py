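"""Brain-behavior correlation machinery.

Time-resolved Spearman rank correlations between a per-participant
behavioral effect and a participant x time neural measure, with
cluster-corrected permutation inference (independent shuffles of the
behavioral vector against the neural data). A robust *skipped* variant
removes bivariate outliers per timepoint — points flagged by the box-plot
(ideal-fourths) rule on projections through a coordinatewise-median centre
— before correlating, and keeps those exclusions fixed during permutation.

Also provides the post hoc power of the correlation test via the Fisher-z
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .group_stats import (
    Cluster,
    ClusterResult,
    GroupTimecourse,
    _build_result,
    _find_clusters,
    _pvalues,
    _row_max_masses,
)

__all__ = [
    "CorrelationTimecourse",
    "critical_rho",
    "timeresolved_correlation",
    "skipped_spearman",
    "correlation_power",
]


@dataclass
class CorrelationTimecourse:
    rho: np.ndarray
    times_ms: np.ndarray
    method: str
    outlier_mask: np.ndarray     # participants x time; all False for 'spearman'
    clusters: ClusterResult
    params: dict = field(default_factory=dict)


def critical_rho(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Spearman rho via the t approximation of its null."""
    if n < 4:
        raise ValueError("need n >= 4")
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit ** 2))


def _rank_corr(x_ranks_c: np.ndarray, y_ranks_c: np.ndarray) -> np.ndarray:
    """Pearson on centred ranks; x ``(n,)`` or ``(R, n)``, y ``(n, T)``."""
    ynorm = np.linalg.norm(y_ranks_c, axis=0)
    ynorm = np.where(ynorm > 0, ynorm, np.inf)
    if x_ranks_c.ndim == 1:
        xnorm = np.linalg.norm(x_ranks_c)
        return (x_ranks_c @ y_ranks_c) / (xnorm * ynorm)
    xnorm = np.linalg.norm(x_ranks_c, axis=1, keepdims=True)
    return (x_ranks_c @ y_ranks_c) / (xnorm * ynorm[None, :])


# ---------------------------------------------------------------------------
# skipped correlation
# ---------------------------------------------------------------------------

def _ideal_fourths(v: np.ndarray) -> tuple[float, float]:
    """Lower/upper quartiles by the ideal-fourths interpolation rule."""
    s = np.sort(v)
    n = s.size
    j = int(np.floor(n / 4 + 5 / 12))
    h = n / 4 + 5 / 12 - j
    q1 = (1 - h) * s[j - 1] + h * s[j]
    k = n - j + 1
    q3 = (1 - h) * s[k - 1] + h * s[k - 2]
    return float(q1), float(q3)


def skipped_outliers(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bivariate outlier flags for the skipped correlation.

    Centre = coordinatewise median. Each data point defines a projection
    direction from the centre; all points are projected onto each
    direction, and a point is an outlier if the box-plot rule (ideal
    fourths, 1.5 x IQR fences) flags its projection on any direction.
    """
    pts = np.column_stack([x, y]).astype(float)
    centre = np.median(pts, axis=0)
    d = pts - centre
    out = np.zeros(len(pts), dtype=bool)
    for i in range(len(pts)):
        norm = np.linalg.norm(d[i])
        if norm == 0:
            continue
        u = d[i] / norm
        proj = d @ u
        q1, q3 = _ideal_fourths(proj)
        iqr = q3 - q1
        out |= (proj > q3 + 1.5 * iqr) | (proj < q1 - 1.5 * iqr)
    return out


def skipped_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Spearman correlation after removing bivariate outliers.

    Returns ``(rho, outlier_mask)``. Equals the plain Spearman correlation
    exactly whenever no point is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need matched vectors with n >= 10")
    mask = skipped_outliers(x, y)
    keep = ~mask
    if keep.sum() < 4:
        raise ValueError("fewer than 4 points retained after outlier removal")
    rho = stats.spearmanr(x[keep], y[keep]).statistic
    return float(rho), mask


# ---------------------------------------------------------------------------
# time-resolved correlation
# ---------------------------------------------------------------------------

def timeresolved_correlation(effects: np.ndarray, neural: GroupTimecourse,
                             method: str = "spearman", n_perm: int = 10000,
                             seed: int = 0, alpha_cluster: float = 0.05,
                             alpha: float = 0.05) -> CorrelationTimecourse:
    """Per-timepoint rank correlation with cluster-corrected inference.

    The cluster-forming threshold is the critical rho at ``alpha_cluster``
    (t approximation); cluster mass is the summed rho. The null shuffles
    the behavioral effects against the neural data (one shared shuffle per
    permutation across timepoints, preserving the temporal dependence of
    the neural data). For ``method='skipped'`` the per-timepoint outlier
    exclusions from the observed data also apply during permutation, and
    the threshold adapts to the retained sample size.
    """
    effects = np.asarray(effects, dtype=float)
    X = neural.values
    n, T = X.shape
    if effects.size != n:
        raise ValueError("effects length must equal number of participants")
    if np.all(effects == effects[0]):
        raise ValueError("effects are constant; rank correlation undefined")

    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    perms = np.argsort(rng.random((n_perm, n)), axis=1)

    outlier_mask = np.zeros((n, T), dtype=bool)
    if method == "spearman":
        xr = stats.rankdata(effects)
        xr_c = xr - xr.mean()
        yr = stats.rankdata(X, axis=0)
        yr_c = yr - yr.mean(axis=0)
        rho = _rank_corr(xr_c, yr_c)
        thresh_t = np.full(T, critical_rho(n, alpha_cluster))
        rho_null = _rank_corr(xr_c[perms], yr_c)
    elif method == "skipped":
        rho = np.empty(T)
        thresh_t = np.empty(T)
        rho_null = np.empty((n_perm, T))
        eff_perm = effects[perms]
        for t in range(T):
            mask_t = skipped_outliers(effects, X[:, t])
            outlier_mask[:, t] = mask_t
            keep = np.flatnonzero(~mask_t)
            if keep.size < 4:
                raise ValueError(f"fewer than 4 points retained at timepoint {t}")
            xk = effects[keep]
            yk = X[keep, t]
            rho[t] = stats.spearmanr(xk, yk).statistic
            thresh_t[t] = critical_rho(keep.size, alpha_cluster)
            # shared participant shuffles, applied to the retained subset
            xr_perm = stats.rankdata(eff_perm[:, keep], axis=1)
            xr_perm_c = xr_perm - xr_perm.mean(axis=1, keepdims=True)
            ykr = stats.rankdata(yk)
            ykr_c = (ykr - ykr.mean())[:, None]
            rho_null[:, t] = _rank_corr(xr_perm_c, ykr_c)[:, 0]
    else:
        raise ValueError(f"unknown method {method!r}")

    # threshold may vary over time (skipped): normalise to a unit threshold
    scale = np.where(thresh_t > 0, thresh_t, 1.0)
    clusters_raw = _find_clusters(rho / scale, 1.0)
    # recompute mass on the rho scale
    clusters = [(a, b, float(rho[a:b].sum())) for a, b, _ in clusters_raw]
    params = {"alpha_cluster": alpha_cluster, "n_perm": n_perm,
              "seed": seed, "method": method}
    if clusters:
        null_scaled = rho_null / scale[None, :]
        # mass in rho units: recompute via masked sums on rho_null
        null_max = _row_max_masses(np.where(np.abs(null_scaled) > 1.0, rho_null, 0.0), 0.0)
        pvals = _pvalues(clusters, null_max, n_perm)
    else:
        pvals = []
    cres = _build_result(clusters, pvals, neural.times_ms, rho, alpha, params)
    return CorrelationTimecourse(
        rho=rho, times_ms=neural.times_ms, method=method,
        outlier_mask=outlier_mask, clusters=cres, params=params)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def correlation_power(rho: float, n: int, alpha: float = 0.05,
                      tails: int = 2) -> float:
    """Power to detect a correlation ``rho`` at sample size ``n``.

    Fisher-z approximation: the test statistic ``atanh(r) * sqrt(n - 3)``
    is treated as normal with mean ``atanh(rho) * sqrt(n - 3)`` and unit
    variance; an approximation to the exact-distribution power, accurate to
    a couple of percentage points at moderate n.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    z = np.arctanh(rho) * np.sqrt(n - 3)
    za = stats.norm.ppf(1 - alpha / tails)
    power = stats.norm.cdf(abs(z) - za)
    if tails == 2:
        power += stats.norm.cdf(-abs(z) - za)
    return float(power)
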