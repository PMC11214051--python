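"""Time-resolved neural RDMs from cross-validated pairwise SVM decoding.

For each participant, trials of every stimulus are randomly partitioned into
``n_splits`` splits and subaveraged into pseudo-trials.  Each split in turn
serves as the test set (hold-one-split-out); the channel covariance of
pseudo-trial residuals in the training splits defines a multivariate noise
normalizer ("epoch method": per-time-point covariances averaged over time,
shrunk, inverted via the symmetric inverse square root), which is applied to
both training and test data.  For every unordered stimulus pair and every
time point a linear SVM (C = 1) is trained on the whitened training
pseudo-trials (channel amplitudes at that sample as features) and scored on
the two held-out pseudo-trials.  Accuracies are averaged over folds and over
``n_permutations`` independent split assignments, giving a time x stimulus x
stimulus RDM of decoding accuracies (0.5 = indistinguishable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.covariance import LedoitWolf

from ._svm import _solve_dual, svm_pair_accuracy
from .containers import EpochArray, NeuralRDMSeries

__all__ = [
    "DecodingConfig",
    "PseudoTrialSet",
    "NoiseNormalizer",
    "subaverage",
    "fit_noise_normalizer",
    "pairwise_decode",
    "build_rdm_series",
    "mean_decoding_timecourse",
]


@dataclass
class DecodingConfig:
    n_splits: int = 5
    n_permutations: int = 50
    classifier: str = "linear_svm"
    svm_cost: float = 1.0
    seed: int = 0
    shrinkage_mode: str = "auto"  # auto (Ledoit-Wolf) | fixed
    shrinkage: float = 0.0
    svm_eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.classifier != "linear_svm":
            raise ValueError(f"unsupported classifier {self.classifier!r}")


@dataclass
class PseudoTrialSet:
    """Subaveraged data: ``averages`` is stimulus x split x channels x time."""

    averages: np.ndarray
    counts: np.ndarray  # stimulus x split trial counts
    stimulus_ids: list[str]
    times: np.ndarray

    @property
    def n_splits(self) -> int:
        return self.averages.shape[1]

    def select_splits(self, splits: list[int]) -> "PseudoTrialSet":
        return PseudoTrialSet(
            averages=self.averages[:, splits],
            counts=self.counts[:, splits],
            stimulus_ids=list(self.stimulus_ids),
            times=self.times,
        )


def subaverage(
    epochs: EpochArray, config: DecodingConfig, permutation_index: int = 0
) -> PseudoTrialSet:
    """One random balanced split assignment and the resulting pseudo-trials.

    The assignment is fully determined by ``(config.seed,
    permutation_index)``; within each stimulus, splits are balanced and the
    remainder trials land in randomly chosen splits.
    """
    rng = np.random.default_rng([config.seed, 101, permutation_index])
    kept = epochs.retained("experimental")
    stim = kept.trial_meta["stimulus_id"].to_numpy()
    ids = sorted(set(stim))
    k = config.n_splits
    S = len(ids)
    averages = np.empty((S, k, kept.n_channels, len(kept.times)))
    counts = np.zeros((S, k), dtype=int)
    for si, sid in enumerate(ids):
        idx = np.where(stim == sid)[0]
        if len(idx) < k:
            raise ValueError(
                f"stimulus {sid!r} has {len(idx)} retained trials, fewer than "
                f"n_splits={k}"
            )
        rng.shuffle(idx)
        base, rem = divmod(len(idx), k)
        sizes = np.full(k, base)
        if rem:
            sizes[rng.choice(k, size=rem, replace=False)] += 1
        start = 0
        for a in range(k):
            sl = idx[start : start + sizes[a]]
            start += sizes[a]
            averages[si, a] = kept.data[sl].mean(axis=0)
            counts[si, a] = len(sl)
    return PseudoTrialSet(averages=averages, counts=counts, stimulus_ids=ids, times=kept.times)


@dataclass
class NoiseNormalizer:
    """Whitening by the symmetric inverse square root of the shrunk residual
    channel covariance."""

    whitening_matrix: np.ndarray
    shrinkage: float
    covariance: np.ndarray

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Whiten along the channel axis of (..., channels, time) data."""
        return np.einsum("dc,...ct->...dt", self.whitening_matrix, data)


def _inv_sqrtm(cov: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) <= 0:
        raise np.linalg.LinAlgError(
            "residual covariance is singular; use shrinkage > 0 (or shrinkage_mode='auto')"
        )
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T


def fit_noise_normalizer(
    train: PseudoTrialSet,
    shrinkage_mode: str = "auto",
    shrinkage: float = 0.0,
) -> NoiseNormalizer:
    """Epoch-method noise covariance from training pseudo-trial residuals.

    Residuals are pseudo-trials minus their stimulus mean; the channel
    covariance is estimated across all residual samples (equivalently,
    per-time-point covariances averaged over time) and shrunk toward a
    scaled identity — analytically (Ledoit-Wolf) in ``auto`` mode, by the
    given intensity in ``fixed`` mode.
    """
    if train.n_splits < 2:
        raise ValueError("need at least 2 pseudo-trials per stimulus to form residuals")
    resid = train.averages - train.averages.mean(axis=1, keepdims=True)
    S, k, C, T = resid.shape
    X = resid.transpose(0, 1, 3, 2).reshape(-1, C)
    if shrinkage_mode == "auto":
        lw = LedoitWolf(assume_centered=True).fit(X)
        cov, gamma = lw.covariance_, float(lw.shrinkage_)
    elif shrinkage_mode == "fixed":
        emp = (X.T @ X) / len(X)
        gamma = float(shrinkage)
        cov = (1.0 - gamma) * emp + gamma * (np.trace(emp) / C) * np.eye(C)
    else:
        raise ValueError(f"unknown shrinkage_mode {shrinkage_mode!r}")
    try:
        W = _inv_sqrtm(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(str(err)) from None
    return NoiseNormalizer(whitening_matrix=W, shrinkage=gamma, covariance=cov)


@njit(cache=True)
def _decode_fold(train, test, pairs, cost, eps):  # pragma: no cover - tested via wrappers
    """Pairwise SVM accuracies for one fold.

    train: (stimuli, k_train, time, channels) whitened training pseudo-trials
    test:  (stimuli, time, channels) whitened held-out pseudo-trials
    Returns (n_pairs, time) accuracies; each test vector scores 1/0 and a
    zero decision value scores 0.5.
    """
    n_pairs = pairs.shape[0]
    S, ktr, T, C = train.shape
    n = 2 * ktr
    acc = np.zeros((n_pairs, T))
    Xtr = np.empty((n, C))
    y = np.empty(n)
    for a in range(ktr):
        y[a] = 1.0
        y[ktr + a] = -1.0
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        for t in range(T):
            for a in range(ktr):
                Xtr[a, :] = train[i, a, t, :]
                Xtr[ktr + a, :] = train[j, a, t, :]
            K = Xtr @ Xtr.T
            alpha, b = _solve_dual(K, y, cost, eps, 10000)
            w = np.zeros(C)
            for m in range(n):
                if alpha[m] != 0.0:
                    w += alpha[m] * y[m] * Xtr[m]
            di = test[i, t, :] @ w + b
            dj = test[j, t, :] @ w + b
            s = 0.5 if di == 0.0 else (1.0 if di > 0.0 else 0.0)
            s += 0.5 if dj == 0.0 else (1.0 if dj < 0.0 else 0.0)
            acc[p, t] = 0.5 * s
    return acc


def pairwise_decode(
    pseudo: PseudoTrialSet,
    stim_a: str,
    stim_b: str,
    time_index: int,
    config: DecodingConfig,
) -> float:
    """Hold-one-split-out decoding accuracy for one stimulus pair and sample.

    The noise normalizer is fitted per fold on the training splits of all
    stimuli present in ``pseudo`` and applied to training and test data; both
    held-out pseudo-trials are scored.  Identical class data yield 0.5 by
    construction rather than an exception.
    """
    ia = pseudo.stimulus_ids.index(stim_a)
    ib = pseudo.stimulus_ids.index(stim_b)
    k = pseudo.n_splits
    accs = []
    for fold in range(k):
        train_splits = [s for s in range(k) if s != fold]
        norm = fit_noise_normalizer(
            pseudo.select_splits(train_splits), config.shrinkage_mode, config.shrinkage
        )
        wh = norm.apply(pseudo.averages[:, :, :, [time_index]])[..., 0]  # S x k x C
        Xtr = np.vstack(
            [wh[ia][train_splits], wh[ib][train_splits]]
        )
        y = np.concatenate([np.ones(k - 1), -np.ones(k - 1)])
        Xte = np.vstack([wh[ia][[fold]], wh[ib][[fold]]])
        accs.append(
            svm_pair_accuracy(
                Xtr, y, Xte, np.array([1.0, -1.0]), C=config.svm_cost, eps=config.svm_eps
            )
        )
    return float(np.mean(accs))


def build_rdm_series(
    epochs: EpochArray, config: DecodingConfig, participant_id: str = ""
) -> NeuralRDMSeries:
    """Full time-resolved RDM: mean pairwise accuracy over folds and
    permutations for every unordered stimulus pair, mirrored into a
    symmetric matrix with a NaN diagonal."""
    first = subaverage(epochs, config, 0)
    S = len(first.stimulus_ids)
    T = len(first.times)
    pairs = np.array([(i, j) for i in range(S) for j in range(i + 1, S)], dtype=np.int64)
    acc = np.zeros((len(pairs), T))
    for perm in range(config.n_permutations):
        pseudo = first if perm == 0 else subaverage(epochs, config, perm)
        k = pseudo.n_splits
        for fold in range(k):
            train_splits = [s for s in range(k) if s != fold]
            norm = fit_noise_normalizer(
                pseudo.select_splits(train_splits), config.shrinkage_mode, config.shrinkage
            )
            wh = norm.apply(pseudo.averages)  # S x k x C x T
            train = np.ascontiguousarray(wh[:, train_splits].transpose(0, 1, 3, 2))
            test = np.ascontiguousarray(wh[:, fold].transpose(0, 2, 1))
            acc += _decode_fold(train, test, pairs, config.svm_cost, config.svm_eps)
    acc /= config.n_permutations * config.n_splits
    values = np.full((T, S, S), np.nan)
    for p, (i, j) in enumerate(pairs):
        values[:, i, j] = acc[p]
        values[:, j, i] = acc[p]
    return NeuralRDMSeries(
        values=values,
        times=first.times,
        items=first.stimulus_ids,
        participant_id=participant_id,
    )


def mean_decoding_timecourse(series: NeuralRDMSeries) -> np.ndarray:
    """Mean decoding accuracy over the strict upper triangle per time point."""
    S = series.n_items
    iu = np.triu_indices(S, k=1)
    return series.values[:, iu[0], iu[1]].mean(axis=1)
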