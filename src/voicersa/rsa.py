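"""Time-resolved partial Spearman correlation between neural and model RDMs.

Each model correlates, at every time point, the vectorized neural RDM with a
characteristic's behavioral RDM after partialling out a fixed covariate set:

* Model 0 — no covariates (plain Spearman);
* Model 1 — the LTAS cosine RDM;
* Model 2 — LTAS plus the acoustic principal-component RDMs;
* Model 3 — Model 2 covariates plus the behavioral RDMs of all other
  retained characteristics.

The partial rank correlation ranks every vector (average ranks on ties),
residualizes the ranked target and neural vectors on the ranked covariates
plus an intercept by least squares, and correlates the residuals; with no
covariates this reduces exactly to Spearman's rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .acoustic import AcousticRDMSet
from .containers import RDM, NeuralRDMSeries

__all__ = [
    "ModelSpec",
    "RSATimeCourse",
    "vectorize_rdm",
    "spearman_partial",
    "run_model",
    "run_all_models",
    "model_covariates",
]

MODEL_IDS = ("M0", "M1", "M2", "M3")


@dataclass
class ModelSpec:
    model_id: str
    target_characteristic: str
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if self.target_characteristic in self.covariate_names:
            raise ValueError("target must not be among the covariates")


@dataclass
class RSATimeCourse:
    """Partial-correlation time course: ``rho`` is participants x time."""

    rho: np.ndarray
    times: np.ndarray
    model: ModelSpec
    participant_ids: list[str] = field(default_factory=list)


def vectorize_rdm(rdm: np.ndarray | RDM, atol: float = 1e-8) -> np.ndarray:
    """Strict lower triangle in row-major order (row i, columns j < i).

    Length n(n-1)/2; symmetric counterpart cells must agree within ``atol``
    (NaN diagonals are ignored).
    """
    m = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("RDM must be square")
    il = np.tril_indices(m.shape[0], k=-1)
    upper = m.T[il]
    lower = m[il]
    if not np.allclose(lower, upper, atol=atol, equal_nan=True):
        raise ValueError("matrix is asymmetric beyond tolerance")
    return lower


def spearman_partial(
    x: np.ndarray, y: np.ndarray, covariates: list[np.ndarray] | None = None
) -> float:
    """Partial Spearman rank correlation of x and y given covariates.

    All vectors are rank-transformed (average ranks); ranked x and y are
    residualized on the ranked covariates plus an intercept, and the Pearson
    correlation of the residuals is returned.  Degenerate cases (constant
    input after ranking, covariate collinear with x or y) return NaN with a
    warning instead of a spurious number.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    covariates = covariates or []
    n = len(x)
    if len(y) != n or any(len(c) != n for c in covariates):
        raise ValueError("all vectors must share one length")
    if n < 4 + len(covariates):
        raise ValueError("too few observations for the requested partialling")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant vector: partial Spearman undefined")
        return float("nan")
    if covariates:
        Z = np.column_stack([np.ones(n)] + [rankdata(c) for c in covariates])
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        tol = 1e-10 * n
        if np.sum(rx**2) < tol or np.sum(ry**2) < tol:
            warnings.warn("covariates explain x or y entirely: partial Spearman undefined")
            return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def run_model(
    neural: NeuralRDMSeries,
    target: RDM,
    covariates: list[RDM],
    spec: ModelSpec,
) -> RSATimeCourse:
    """One participant's time course for one model and characteristic.

    Covariates are time-invariant and pre-ranked once; an item-ordering
    mismatch between any two RDMs raises before any statistic is computed.
    """
    for other in [target] + covariates:
        if list(other.items) != list(neural.items):
            raise ValueError(
                f"item ordering mismatch between neural RDM and {other.name!r}"
            )
    tv = vectorize_rdm(target)
    cvs = [vectorize_rdm(c) for c in covariates]
    T = len(neural.times)
    rho = np.empty((1, T))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in range(T):
            rho[0, t] = spearman_partial(vectorize_rdm(neural.values[t]), tv, cvs)
    return RSATimeCourse(
        rho=rho,
        times=neural.times,
        model=spec,
        participant_ids=[neural.participant_id],
    )


def model_covariates(
    model_id: str,
    characteristic: str,
    behavioral: dict[str, RDM],
    acoustic: AcousticRDMSet,
) -> list[RDM]:
    """Covariate RDMs implied by the model definition."""
    if model_id == "M0":
        return []
    cov = [acoustic.ltas_rdm]
    if model_id in ("M2", "M3"):
        cov += list(acoustic.pc_rdms)
    if model_id == "M3":
        cov += [behavioral[c] for c in behavioral if c != characteristic]
    return cov


def run_all_models(
    neural_by_participant: dict[str, NeuralRDMSeries],
    behavioral: dict[str, RDM],
    acoustic: AcousticRDMSet,
    models: tuple[str, ...] = ("M1", "M2", "M3"),
) -> dict[tuple[str, str], RSATimeCourse]:
    """All participants x retained characteristics x models.

    Returns ``{(characteristic, model_id): RSATimeCourse}`` with the rho
    matrix stacked participants x time in the dict order of
    ``neural_by_participant``.
    """
    if not neural_by_participant:
        raise ValueError("need at least one participant")
    out: dict[tuple[str, str], RSATimeCourse] = {}
    pids = list(neural_by_participant)
    for char, target in behavioral.items():
        for mid in models:
            cov = model_covariates(mid, char, behavioral, acoustic)
            spec = ModelSpec(
                model_id=mid,
                target_characteristic=char,
                covariate_names=[c.name for c in cov],
            )
            rows = []
            times = None
            for pid in pids:
                tc = run_model(neural_by_participant[pid], target, cov, spec)
                rows.append(tc.rho[0])
                times = tc.times
            out[(char, mid)] = RSATimeCourse(
                rho=np.vstack(rows), times=times, model=spec, participant_ids=pids
            )
    return out
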