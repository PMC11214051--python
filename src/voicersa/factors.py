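"""PCA with direct oblimin rotation, shared by the rating and acoustic stages.

Both dimension reductions in the pipeline (person-characteristic ratings and
the 13 acoustic measures) use the same recipe: standardize, eigendecompose
the correlation matrix, retain components with eigenvalue > 1 (Kaiser), and
rotate the retained loadings obliquely by direct oblimin with gamma = 0
(direct quartimin).  The rotation is found with the gradient-projection
algorithm of Jennrich (2002) as formulated for oblique rotation by Bernaards
& Jennrich (2005); the oblique rotation leaves the reconstructed correlation
contribution Lambda Phi Lambda' of the retained components invariant, which
the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PCASolution", "pca_oblimin"]


@dataclass
class PCASolution:
    """Retained-component PCA solution after oblique rotation.

    ``pattern_loadings`` (variables x components) are the rotated pattern
    coefficients; ``factor_correlations`` is Phi = T'T of the rotation;
    ``variance_explained_pct`` is the cumulative unrotated eigenvalue share
    of the retained components; ``component_scores`` (items x components) are
    regression-method scores with unit variance before rotation.
    """

    n_components: int
    eigenvalues: np.ndarray
    pattern_loadings: np.ndarray
    factor_correlations: np.ndarray
    variance_explained_pct: float
    component_scores: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    item_names: list[str] = field(default_factory=list)
    rotation_iterations: int = 0


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion value and gradient wrt the loadings."""
    k = L.shape[1]
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    M = L2 @ N
    f = float(np.sum(L2 * M)) / 4.0
    return f, L * M


def _gpf_oblique(
    A: np.ndarray, max_iter: int = 1000, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, int]:
    """Gradient-projection oblique rotation minimizing the quartimin criterion.

    Returns (pattern loadings, factor correlations, iterations); raises on
    non-convergence.
    """
    k = A.shape[1]
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    for it in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = float(np.sqrt(np.sum(Gp**2)))
        if s < tol:
            Phi = T.T @ T
            return L, Phi, it
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            Tt = X / np.sqrt(np.sum(X**2, axis=0))
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    raise RuntimeError(
        f"oblimin rotation did not converge in {max_iter} iterations "
        f"(last gradient norm {s:.3e}, criterion {f:.6e})"
    )


def pca_oblimin(
    X: np.ndarray,
    retain_rule: str = "eigenvalue_gt_1",
    variable_names: list[str] | None = None,
    item_names: list[str] | None = None,
) -> PCASolution:
    """Standardize, PCA on the correlation matrix, retain eigenvalue > 1,
    oblimin-rotate.

    With a single retained component the rotation is the identity (up to the
    sign convention that the largest-magnitude loading is positive, applied
    to every component).
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [i for i in range(p) if sd[i] == 0]
        raise ValueError(f"constant variables cannot be standardized: columns {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if retain_rule != "eigenvalue_gt_1":
        raise ValueError(f"unknown retain rule {retain_rule!r}")
    k = max(1, int(np.sum(evals > 1.0)))
    A = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))

    if k == 1:
        L, Phi, iters = A.copy(), np.eye(1), 0
    else:
        L, Phi, iters = _gpf_oblique(A)

    # sign convention: dominant loading of each component positive
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)

    # regression-method component scores from the rotated structure matrix
    S = L @ Phi
    B = np.linalg.solve(R, S)
    scores = Z @ B

    return PCASolution(
        n_components=k,
        eigenvalues=evals,
        pattern_loadings=L,
        factor_correlations=Phi,
        variance_explained_pct=float(100.0 * np.sum(evals[:k]) / p),
        component_scores=scores,
        variable_names=list(variable_names) if variable_names else [f"v{i}" for i in range(p)],
        item_names=list(item_names) if item_names else [str(i) for i in range(n)],
        rotation_iterations=iters,
    )
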