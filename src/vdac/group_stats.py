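"""Group-level inference on decoding timecourses.

Significance over time is assessed with cluster-based permutation tests:
per-timepoint t statistics are thresholded at the two-tailed critical value
for the cluster-forming alpha, contiguous suprathreshold runs form clusters
whose mass is the summed t, and family-wise control comes from comparing
each observed mass with the permutation distribution of the maximum
absolute cluster mass (sign flips of participants for one-sample/paired
tests, group re-partitions for independent tests). The observed statistic
is included in the null (the +1 rule), so the smallest attainable p is
exactly ``1 / (n_perm + 1)``.

Baseline (pre-onset) timepoints should be excluded before testing; see
:meth:`GroupTimecourse.crop`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupTimecourse",
    "Cluster",
    "ClusterResult",
    "cluster_sign_permutation",
    "cluster_independent_permutation",
    "median_split",
]


@dataclass
class GroupTimecourse:
    """Participant x time matrix of a summary statistic (e.g. mean delta)."""

    values: np.ndarray
    times_ms: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.times_ms.size:
            raise ValueError("values must be n_participants x n_times")
        if not np.isfinite(self.values).all():
            raise ValueError("GroupTimecourse contains non-finite values")

    def crop(self, start_ms: float, end_ms: float = np.inf) -> "GroupTimecourse":
        """Restrict to ``start_ms <= t <= end_ms`` (e.g. drop the baseline)."""
        m = (self.times_ms >= start_ms) & (self.times_ms <= end_ms)
        return GroupTimecourse(self.values[:, m], self.times_ms[m], self.label)


@dataclass
class Cluster:
    t_start_ms: float
    t_end_ms: float
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    sig_mask: np.ndarray
    times_ms: np.ndarray
    t_obs: np.ndarray
    params: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]

    def onset_ms(self, alpha: float = 0.05) -> float:
        """Earliest start of a significant cluster (NaN when none)."""
        sig = self.significant(alpha)
        return min(c.t_start_ms for c in sig) if sig else float("nan")


# ---------------------------------------------------------------------------
# cluster machinery
# ---------------------------------------------------------------------------

def _find_clusters(stat: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    """Maximal runs with |stat| above threshold, same sign throughout.

    Returns ``(start, stop_exclusive, mass)`` triples, mass = summed stat.
    """
    out = []
    for sign in (1.0, -1.0):
        mask = sign * stat > thresh
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        for a, b in zip(starts, stops):
            out.append((int(a), int(b), float(stat[a:b].sum())))
    return sorted(out)


def _row_max_masses(stat: np.ndarray, thresh: float) -> np.ndarray:
    """Max absolute cluster mass per row of an ``R x T`` statistic matrix.

    Vectorised over rows (each row is one permutation); two-sided: positive
    and negative clusters compete for the maximum.
    """
    R, T = stat.shape
    out = np.zeros(R)
    for sign in (1.0, -1.0):
        s = sign * stat
        mask = np.zeros((R, T + 1), dtype=bool)
        mask[:, :T] = s > thresh
        vals = np.zeros((R, T + 1))
        vals[:, :T] = np.where(mask[:, :T], s, 0.0)
        flat_mask = mask.ravel()
        d = np.diff(np.concatenate([[0], flat_mask.view(np.int8)]))
        starts = np.flatnonzero(d == 1)
        if starts.size == 0:
            continue
        stops = np.flatnonzero(d == -1)
        csum = np.concatenate([[0.0], np.cumsum(vals.ravel())])
        masses = csum[stops] - csum[starts]
        rows = starts // (T + 1)
        np.maximum.at(out, rows, masses)
    return out


def _pvalues(clusters: list[tuple[int, int, float]], null_max: np.ndarray,
             n_perm: int) -> list[float]:
    return [float((1 + np.sum(null_max >= abs(m))) / (n_perm + 1))
            for _, _, m in clusters]


def _build_result(clusters, pvals, times_ms, t_obs, alpha, params) -> ClusterResult:
    out = []
    sig_mask = np.zeros(times_ms.size, dtype=bool)
    for (a, b, m), p in zip(clusters, pvals):
        out.append(Cluster(float(times_ms[a]), float(times_ms[b - 1]), m, p))
        if p <= alpha:
            sig_mask[a:b] = True
    return ClusterResult(out, sig_mask, times_ms, t_obs, params)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def cluster_sign_permutation(g: GroupTimecourse, alpha_cluster: float = 0.05,
                             n_perm: int = 10000, seed: int = 0,
                             alpha: float = 0.05) -> ClusterResult:
    """One-sample cluster test against zero via participant sign flips.

    Paired condition contrasts are tested by passing participant-wise
    difference timecourses. The cluster-forming threshold is the two-tailed
    critical t at ``alpha_cluster``; the null is the maximum absolute
    cluster mass over random sign flips of whole participants.
    """
    X = g.values
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 participants, got {n}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    t_obs = np.divide(mean, sd / np.sqrt(n), out=np.zeros_like(mean), where=sd > 0)
    thresh = stats.t.ppf(1 - alpha_cluster / 2, n - 1)
    clusters = _find_clusters(t_obs, thresh)
    params = {"alpha_cluster": alpha_cluster, "n_perm": n_perm,
              "sidedness": "two-sided", "seed": seed, "test": "sign"}
    if not clusters:
        return _build_result([], [], g.times_ms, t_obs, alpha, params)

    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    m_null = signs @ X / n                                      # (n_perm, T)
    msq = np.mean(X ** 2, axis=0)                               # flip-invariant
    var = (msq[None, :] - m_null ** 2) * n / (n - 1)
    var = np.clip(var, 1e-300, None)
    t_null = m_null / np.sqrt(var / n)
    null_max = _row_max_masses(t_null, thresh)
    pvals = _pvalues(clusters, null_max, n_perm)
    return _build_result(clusters, pvals, g.times_ms, t_obs, alpha, params)


def _independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1 / na + 1 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    return np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)


def cluster_independent_permutation(a: GroupTimecourse, b: GroupTimecourse,
                                    n_perm: int = 10000, seed: int = 0,
                                    alpha_cluster: float = 0.05,
                                    alpha: float = 0.05) -> ClusterResult:
    """Two-group cluster test; null from random re-partitions of participants.

    Used for the strong- vs weak-capture median-split comparison: per
    timepoint an independent-samples (pooled-variance) t, clusters as in
    the one-sample test, the null built by shuffling group membership while
    preserving group sizes.
    """
    na, nb = a.values.shape[0], b.values.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 participants")
    if not np.array_equal(a.times_ms, b.times_ms):
        raise ValueError("groups must share one time axis")
    t_obs = _independent_t(a.values, b.values)
    n = na + nb
    thresh = stats.t.ppf(1 - alpha_cluster / 2, n - 2)
    clusters = _find_clusters(t_obs, thresh)
    params = {"alpha_cluster": alpha_cluster, "n_perm": n_perm,
              "sidedness": "two-sided", "seed": seed, "test": "independent"}
    if not clusters:
        return _build_result([], [], a.times_ms, t_obs, alpha, params)

    Z = np.vstack([a.values, b.values])
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    null_max = np.empty(n_perm)
    chunk = max(1, int(5e7 // (n * Z.shape[1])))
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        idx = np.argsort(rng.random((hi - lo, n)), axis=1)
        ga = Z[idx[:, :na]]                                     # (c, na, T)
        gb = Z[idx[:, na:]]
        va = ga.var(axis=1, ddof=1)
        vb = gb.var(axis=1, ddof=1)
        sp = ((na - 1) * va + (nb - 1) * vb) / (n - 2)
        denom = np.sqrt(np.clip(sp, 1e-300, None) * (1 / na + 1 / nb))
        t_null = (ga.mean(axis=1) - gb.mean(axis=1)) / denom
        null_max[lo:hi] = _row_max_masses(t_null, thresh)
    pvals = _pvalues(clusters, null_max, n_perm)
    return _build_result(clusters, pvals, a.times_ms, t_obs, alpha, params)


def median_split(effects: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split participants into weak/strong halves by effect magnitude.

    Returns ``(weak_idx, strong_idx)``: the lower half of the sorted
    effects and the upper half; with odd n the median participant joins the
    upper (strong) half. Ties are broken by participant index, so the
    assignment is deterministic.
    """
    effects = np.asarray(effects, dtype=float)
    n = effects.size
    if n < 4:
        raise ValueError("need at least 4 participants for a median split")
    order = np.lexsort((np.arange(n), effects))   # effect, then index
    half = n // 2
    weak = np.sort(order[:half])
    strong = np.sort(order[half:])
    return weak, strong
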