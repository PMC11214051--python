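"""Group-level permutation-based cluster-size inference and effect sizes.

Per time point a one-sample t statistic (against zero) is converted to a z
value through the probability-integral transform; contiguous runs of
suprathreshold samples (z > 1.64 one-sided, |z| > 1.96 two-sided; strict
inequality) form clusters scored by their size in samples.  The null
distribution of the maximum cluster size is built by sign-flipping whole
participant time courses (the exact randomization test under a symmetric
null), and a cluster's corrected p value is the add-one fraction of null
maxima at least as large.  Paired model-vs-model comparisons analyze the
participant-wise difference two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "InferenceConfig",
    "Cluster",
    "ClusterResult",
    "TimeCourseStats",
    "normal_quantile_threshold",
    "cluster_onesample",
    "cluster_paired",
    "peak_statistics",
]


@dataclass
class InferenceConfig:
    z_threshold_one_sided: float = 1.64
    z_threshold_two_sided: float = 1.96
    n_iterations: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    cluster_statistic: str = "size"  # size | mass

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100")
        if not (self.z_threshold_one_sided > 0 and self.z_threshold_two_sided > 0):
            raise ValueError("thresholds must be positive")


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    start_index: int
    end_index: int
    size: int
    cluster_z: float  # peak |z| within the cluster
    corrected_p: float
    sign: int = 1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    z_values: np.ndarray
    times: np.ndarray
    peak_time_ms: float
    peak_statistic: float
    config: InferenceConfig

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.config.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.corrected_p < a]


@dataclass
class TimeCourseStats:
    t_value: float
    df: int
    cohens_d: float
    time_ms: float
    mean: float


def normal_quantile_threshold(alpha: float, sides: str = "one") -> float:
    """z threshold for tail probability ``alpha`` (one- or two-sided)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sides == "one":
        return float(stats.norm.isf(alpha))
    if sides == "two":
        return float(stats.norm.isf(alpha / 2.0))
    raise ValueError("sides must be 'one' or 'two'")


def _t_to_z(tvals: np.ndarray, df: int) -> np.ndarray:
    """Probability-integral transform t -> z, numerically stable per tail."""
    t = np.asarray(tvals, dtype=np.float64)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
    return z


def _t_map(data: np.ndarray) -> np.ndarray:
    """One-sample t per column of a participants x time matrix; columns with
    zero variance yield NaN."""
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end inclusive) of each run of True in a 1-D mask."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0] - 1
    return list(zip(starts, ends))


def _cluster_score(z: np.ndarray, start: int, end: int, statistic: str, thr: float) -> float:
    if statistic == "size":
        return float(end - start + 1)
    return float(np.sum(np.abs(z[start : end + 1]) - thr))


def _max_null_score(
    data: np.ndarray, config: InferenceConfig, thr: float, two_sided: bool
) -> np.ndarray:
    """Max cluster score per sign-flip iteration (vectorized t computation)."""
    n, T = data.shape
    rng = np.random.default_rng([config.seed, 211])
    signs = rng.choice([-1.0, 1.0], size=(config.n_iterations, n))
    m = signs @ data / n
    sumsq = np.sum(data**2, axis=0)  # invariant under sign flips
    var = np.maximum(sumsq - n * m**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t[var == 0] = np.nan
    z = _t_to_z(np.nan_to_num(t, nan=0.0), n - 1)
    z[np.isnan(t)] = 0.0
    exceed = (np.abs(z) > thr) if two_sided else (z > thr)
    out = np.zeros(config.n_iterations)
    for i in range(config.n_iterations):
        best = 0.0
        for s, e in _find_runs(exceed[i]):
            score = _cluster_score(z[i], s, e, config.cluster_statistic, thr)
            if score > best:
                best = score
        out[i] = best
    return out


def _cluster_test(
    data: np.ndarray, times: np.ndarray, config: InferenceConfig, two_sided: bool
) -> ClusterResult:
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    thr = config.z_threshold_two_sided if two_sided else config.z_threshold_one_sided
    t = _t_map(data)
    if np.any(np.isnan(t)):
        warnings.warn("zero-variance time points excluded from clusters")
    df = n - 1
    z = np.where(np.isnan(t), np.nan, _t_to_z(np.nan_to_num(t, nan=0.0), df))
    finite_z = np.nan_to_num(z, nan=0.0)
    exceed = (np.abs(finite_z) > thr) if two_sided else (finite_z > thr)
    exceed &= ~np.isnan(z)
    runs = _find_runs(exceed)
    null_max = _max_null_score(data, config, thr, two_sided) if runs else np.array([])
    clusters = []
    for s, e in runs:
        score = _cluster_score(finite_z, s, e, config.cluster_statistic, thr)
        p = (1.0 + np.sum(null_max >= score)) / (1.0 + config.n_iterations)
        seg = finite_z[s : e + 1]
        peak = seg[np.argmax(np.abs(seg))]
        clusters.append(
            Cluster(
                start_ms=float(times[s]),
                end_ms=float(times[e]),
                start_index=int(s),
                end_index=int(e),
                size=int(e - s + 1),
                cluster_z=float(peak),
                corrected_p=float(p),
                sign=int(np.sign(peak)) or 1,
            )
        )
    sig = [c for c in clusters if c.corrected_p < config.alpha]
    gm = data.mean(axis=0)
    if sig:
        idx = np.concatenate([np.arange(c.start_index, c.end_index + 1) for c in sig])
        peak_idx = idx[np.argmax(gm[idx])]
    else:
        peak_idx = int(np.argmax(gm))
    return ClusterResult(
        clusters=clusters,
        z_values=z,
        times=np.asarray(times, dtype=np.float64),
        peak_time_ms=float(times[peak_idx]),
        peak_statistic=float(gm[peak_idx]),
        config=config,
    )


def cluster_onesample(
    data: np.ndarray, times: np.ndarray, config: InferenceConfig
) -> ClusterResult:
    """One-sided cluster-size inference of a participants x time matrix
    against zero (z > ``z_threshold_one_sided``)."""
    return _cluster_test(data, times, config, two_sided=False)


def cluster_paired(
    data_a: np.ndarray, data_b: np.ndarray, times: np.ndarray, config: InferenceConfig
) -> ClusterResult:
    """Two-sided cluster inference on matched-participant differences a - b."""
    a = np.asarray(data_a, dtype=np.float64)
    b = np.asarray(data_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired matrices must have matching shapes")
    return _cluster_test(a - b, times, config, two_sided=True)


def peak_statistics(
    data: np.ndarray,
    times: np.ndarray,
    null_value: float = 0.0,
    clusters: list[Cluster] | None = None,
) -> TimeCourseStats:
    """t, df and Cohen's d at the group-mean peak.

    The peak is the maximum of the group mean, restricted to significant
    clusters when provided; ties resolve to the earliest time point.  The
    test is one-sample against ``null_value`` (0 for correlations, 0.5 for
    decoding accuracy) and d = (mean - null) / SD.
    """
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    gm = data.mean(axis=0)
    if clusters:
        idx = np.concatenate(
            [np.arange(c.start_index, c.end_index + 1) for c in clusters]
        )
    else:
        idx = np.arange(len(gm))
    peak_idx = int(idx[np.argmax(gm[idx])])  # argmax returns first max: earliest wins
    x = data[:, peak_idx] - null_value
    sd = x.std(ddof=1)
    t = x.mean() / (sd / np.sqrt(n)) if sd > 0 else np.inf * np.sign(x.mean())
    d = x.mean() / sd if sd > 0 else np.inf * np.sign(x.mean())
    return TimeCourseStats(
        t_value=float(t),
        df=n - 1,
        cohens_d=float(d),
        time_ms=float(times[peak_idx]),
        mean=float(gm[peak_idx]),
    )
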