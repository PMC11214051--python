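"""Acoustic dissimilarity structure: LTAS and perceptually salient measures.

Two families of acoustic RDMs enter the models as covariates:

* the cosine dissimilarity between long-term average spectra (LTAS), which
  captures overarching spectral-shape differences (vowel category, spectral
  tilt, formant structure);
* absolute score differences on the principal components of 13 perceptually
  salient acoustic measures (F0, formants and their dispersion, harmonic
  source shape, CPP, energy, HNR), reduced by PCA with oblimin rotation.

Extraction of F0/formant/voice-quality measures from audio is delegated to
external tools; this module consumes the feature table.  The LTAS itself is
computed here from waveforms (Welch-averaged periodogram).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import cosine as _scipy_cosine

from .containers import RDM
from .factors import PCASolution, pca_oblimin

__all__ = [
    "LTASMatrix",
    "AcousticRDMSet",
    "compute_ltas",
    "ltas_from_waveforms",
    "cosine_dissimilarity",
    "formant_dispersion",
    "ltas_rdm",
    "acoustic_pca_rdms",
]


@dataclass
class LTASMatrix:
    """Per-stimulus long-term average spectra on a common frequency grid.

    ``spectra`` is stimulus x frequency-bin power; ``domain`` records whether
    values are linear power or dB.  Dissimilarities are computed on linear
    power (a dB offset would distort the angle between spectra).
    """

    spectra: np.ndarray
    freqs: np.ndarray
    bin_hz: float
    fmax: float
    items: list[str]
    domain: str = "linear"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        if self.spectra.shape != (len(self.items), len(self.freqs)):
            raise ValueError("spectra must be items x frequency bins")
        if self.domain == "linear" and np.any(self.spectra < 0):
            raise ValueError("linear-domain spectra must be non-negative")

    def to_linear(self) -> np.ndarray:
        if self.domain == "linear":
            return self.spectra
        return 10.0 ** (self.spectra / 10.0)

    def to_db(self) -> np.ndarray:
        if self.domain == "db":
            return self.spectra
        return 10.0 * np.log10(np.maximum(self.spectra, 1e-300))


@dataclass
class AcousticRDMSet:
    ltas_rdm: RDM
    pc_rdms: list[RDM]
    pca: PCASolution

    def covariates(self) -> list[RDM]:
        return [self.ltas_rdm] + list(self.pc_rdms)


def compute_ltas(
    waveform: np.ndarray, sfreq: float, bin_hz: float = 100.0, fmax: float = 8000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Long-term average spectrum of one recording, in dB.

    Welch-averaged periodogram with segment length chosen so the bin width
    equals ``bin_hz``; returns (freqs, power_db) for bins up to ``fmax``.
    """
    waveform = np.asarray(waveform, dtype=np.float64).ravel()
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if not np.any(waveform):
        raise ValueError("silent (all-zero) waveform has no spectrum")
    if fmax > sfreq / 2:
        raise ValueError("fmax exceeds the Nyquist frequency")
    nperseg = int(round(sfreq / bin_hz))
    nperseg = min(nperseg, waveform.size)
    freqs, pxx = sps.welch(waveform, fs=sfreq, nperseg=nperseg, window="hann")
    keep = freqs <= fmax
    return freqs[keep], 10.0 * np.log10(np.maximum(pxx[keep], 1e-300))


def ltas_from_waveforms(
    waveforms: dict[str, np.ndarray], sfreq: float, bin_hz: float = 100.0, fmax: float = 8000.0
) -> LTASMatrix:
    """Stack per-stimulus LTAS (linear power) into an :class:`LTASMatrix`."""
    items = list(waveforms)
    rows = []
    freqs = None
    for sid in items:
        f, db = compute_ltas(waveforms[sid], sfreq, bin_hz=bin_hz, fmax=fmax)
        freqs = f
        rows.append(10.0 ** (db / 10.0))
    return LTASMatrix(
        spectra=np.vstack(rows), freqs=freqs, bin_hz=bin_hz, fmax=fmax, items=items,
        domain="linear",
    )


def cosine_dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); 0 for proportional vectors, up to 2 for opposed ones."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if not np.any(u) or not np.any(v):
        raise ValueError("cosine dissimilarity undefined for zero vectors")
    return float(_scipy_cosine(u, v))


def formant_dispersion(formants: np.ndarray, method: str = "regression") -> float:
    """Formant dispersion DF (Hz) from the first four formants.

    ``regression`` (default): slope of the least-squares fit of formant
    frequency against the odd-quarter-wavelength positions (2i-1)/2 — the
    regression reading of the Reby & McComb formulation.  ``spacing``:
    mean adjacent spacing (F4 - F1) / 3.  The two agree exactly when the
    formants form an arithmetic progression.
    """
    f = np.asarray(formants, dtype=np.float64).ravel()
    if f.size != 4:
        raise ValueError("expected F1..F4")
    if np.any(np.diff(f) <= 0):
        raise ValueError(f"formants must be strictly increasing, got {f}")
    if method == "regression":
        x = (2.0 * np.arange(1, 5) - 1.0) / 2.0
        slope = np.polyfit(x, f, 1)[0]
        return float(slope)
    if method == "spacing":
        return float((f[3] - f[0]) / 3.0)
    raise ValueError(f"unknown method {method!r}")


def ltas_rdm(ltas: LTASMatrix) -> RDM:
    """Pairwise cosine dissimilarity of linear-power spectra."""
    x = ltas.to_linear()
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero spectrum in LTAS matrix")
    g = (x @ x.T) / np.outer(norms, norms)
    vals = 1.0 - np.clip(g, -1.0, 1.0)
    np.fill_diagonal(vals, 0.0)
    vals = 0.5 * (vals + vals.T)
    return RDM(values=vals, items=list(ltas.items), kind="cosine_ltas", name="LTAS")


def acoustic_pca_rdms(
    features: pd.DataFrame, ltas: LTASMatrix, feature_columns: list[str] | None = None
) -> AcousticRDMSet:
    """PCA (oblimin) over the 13 acoustic measures plus the LTAS cosine RDM.

    Components with eigenvalue > 1 are retained; each yields an RDM of
    absolute component-score differences between stimuli.
    """
    from .synthetic import ACOUSTIC_MEASURES

    if feature_columns is None:
        feature_columns = [c for c in ACOUSTIC_MEASURES if c in features.columns]
    if len(feature_columns) < 2:
        raise ValueError("need at least two acoustic measures")
    items = list(features["stimulus_id"]) if "stimulus_id" in features.columns else [
        str(i) for i in range(len(features))
    ]
    if items != list(ltas.items):
        raise ValueError("feature table and LTAS matrix must list the same stimuli in order")
    X = features[feature_columns].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("acoustic features must be complete and finite")
    pca = pca_oblimin(X, variable_names=feature_columns, item_names=items)
    if pca.n_components < 1:
        raise ValueError("no acoustic component reached the eigenvalue > 1 criterion")
    pc_rdms = []
    for k in range(pca.n_components):
        s = pca.component_scores[:, k]
        vals = np.abs(s[:, None] - s[None, :])
        pc_rdms.append(RDM(values=vals, items=items, kind="abs_pc_diff", name=f"PC{k + 1}"))
    return AcousticRDMSet(ltas_rdm=ltas_rdm(ltas), pc_rdms=pc_rdms, pca=pca)
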