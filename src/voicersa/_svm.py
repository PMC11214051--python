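"""Minimal linear C-SVC solver for tiny pairwise decoding problems.

Pairwise decoding trains a two-class linear SVM on a handful of pseudo-trials
(typically 4 per class) for every stimulus pair x time point x fold x
permutation — millions of fits per participant.  General-purpose SVM wrappers
spend orders of magnitude more time on input validation than on the
optimization itself at this problem size, so the dual problem is solved
directly here with the standard SMO algorithm using maximal-violating-pair
working-set selection (the libsvm strategy).  Equivalence with libsvm on
random problems is asserted in the test suite.

Dual problem (C-SVC):

    min_a  0.5 a' Q a - e' a   s.t.  0 <= a_i <= C,  y' a = 0

with Q_ij = y_i y_j K_ij and K the linear kernel.  The bias follows from the
KKT conditions: b = -y_i g_i for any free support vector (averaged), where
g = Q a - e is the dual gradient.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["svm_decision_values", "svm_pair_accuracy"]


@njit(cache=True)
def _solve_dual(K, y, C, eps, max_iter):  # pragma: no cover - exercised via wrappers
    n = K.shape[0]
    alpha = np.zeros(n)
    g = -np.ones(n)
    it = 0
    while it < max_iter:
        it += 1
        i = -1
        j = -1
        gmax = -1e300
        gmin = 1e300
        for t in range(n):
            yg = -y[t] * g[t]
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                if yg > gmax:
                    gmax = yg
                    i = t
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                if yg < gmin:
                    gmin = yg
                    j = t
        if i < 0 or j < 0 or gmax - gmin < eps:
            break
        a = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if a <= 0.0:
            a = 1e-12
        d = (gmax - gmin) / a
        # feasible step range for alpha_i += y_i d, alpha_j -= y_j d
        if y[i] > 0.0:
            lo_i, hi_i = -alpha[i], C - alpha[i]
        else:
            lo_i, hi_i = alpha[i] - C, alpha[i]
        if y[j] > 0.0:
            lo_j, hi_j = alpha[j] - C, alpha[j]
        else:
            lo_j, hi_j = -alpha[j], C - alpha[j]
        lo = max(lo_i, lo_j)
        hi = min(hi_i, hi_j)
        if d > hi:
            d = hi
        elif d < lo:
            d = lo
        dai = y[i] * d
        daj = -y[j] * d
        alpha[i] += dai
        alpha[j] += daj
        # snap to the box so bound/free classification stays exact
        for t in (i, j):
            if alpha[t] < 1e-12:
                alpha[t] = 0.0
            elif alpha[t] > C - 1e-12:
                alpha[t] = C
        for t in range(n):
            g[t] += y[t] * (y[i] * K[t, i] * dai + y[j] * K[t, j] * daj)
    # bias from the KKT interval
    gmax = -1e300
    gmin = 1e300
    nfree = 0
    sfree = 0.0
    for t in range(n):
        yg = -y[t] * g[t]
        if 0.0 < alpha[t] < C:
            nfree += 1
            sfree += yg
        else:
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                if yg > gmax:
                    gmax = yg
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                if yg < gmin:
                    gmin = yg
    if nfree > 0:
        b = sfree / nfree
    else:
        b = 0.5 * (gmax + gmin)
    return alpha, b


@njit(cache=True)
def _decision_values(X_train, y, X_test, C, eps):  # pragma: no cover
    K = X_train @ X_train.T
    alpha, b = _solve_dual(K, y, C, eps, 10000)
    w = np.zeros(X_train.shape[1])
    for i in range(X_train.shape[0]):
        if alpha[i] != 0.0:
            w += alpha[i] * y[i] * X_train[i]
    return X_test @ w + b


def svm_decision_values(
    X_train: np.ndarray,
    y: np.ndarray,
    X_test: np.ndarray,
    C: float = 1.0,
    eps: float = 1e-3,
) -> np.ndarray:
    """Decision values of a linear C-SVC trained on (X_train, y in {-1,+1}).

    Positive values predict the +1 class; identical in convention to
    ``sklearn.svm.SVC(kernel="linear").decision_function`` with classes
    (-1, +1).
    """
    X_train = np.ascontiguousarray(X_train, dtype=np.float64)
    X_test = np.ascontiguousarray(X_test, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1")
    return _decision_values(X_train, y, X_test, float(C), float(eps))


def svm_pair_accuracy(
    X_train: np.ndarray,
    y: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    C: float = 1.0,
    eps: float = 1e-3,
) -> float:
    """Classification accuracy on X_test; a zero decision value scores 0.5.

    The 0.5 credit makes the degenerate case (identical classes, zero weight
    vector) return chance instead of an arbitrary class.
    """
    d = svm_decision_values(X_train, y, X_test, C=C, eps=eps)
    score = np.where(np.sign(d) == 0.0, 0.5, (np.sign(d) == np.sign(y_test)).astype(float))
    return float(np.mean(score))
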