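"""EEG preprocessing: bad-channel QC, interpolation, artifact flagging,
filtering, baseline correction and re-referencing.

The canonical order is: detect bad channels -> spherical-spline interpolate
-> (optional 100 Hz low-pass) -> flag muscle / amplitude artifacts ->
band-pass 0.1-30 Hz (zero-phase 4th-order Butterworth) -> baseline-correct
on the 100 ms prestimulus window -> re-reference to the TP9/TP10 average.
Artifact rejection only flags trials (``keep_flag``); retained samples are
never altered by the rejection step itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.special import legendre

from .containers import EpochArray

__all__ = [
    "ChannelQCReport",
    "detect_bad_channels",
    "interpolate_channels",
    "reject_amplitude_artifacts",
    "flag_muscle_artifacts",
    "bandpass_filter",
    "lowpass_filter",
    "baseline_correct",
    "rereference",
    "preprocess",
]


@dataclass
class ChannelQCReport:
    bad_channels: list[str]
    per_channel_statistic: np.ndarray
    threshold_sd: float


def detect_bad_channels(epochs: EpochArray, threshold_sd: float = 4.0) -> ChannelQCReport:
    """Joint-probability bad-channel detection in the frequency domain.

    Per channel, the trial-averaged log power spectrum (1-Hz-order bins from
    Welch's method) is scored bin-wise against the robust across-channel
    distribution (median / MAD); the per-channel statistic is the mean
    squared robust z over bins — a joint log-probability up to sign and
    constant under a Gaussian model.  Channels whose statistic deviates more
    than ``threshold_sd`` robust SDs from the channel median are flagged.
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    sf = epochs.sfreq
    x = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    nper = min(x.shape[1], int(sf))  # ~1 Hz resolution
    _, pxx = sps.welch(x, fs=sf, nperseg=nper, axis=-1)
    logp = np.log10(np.maximum(pxx, 1e-300))
    med = np.median(logp, axis=0)
    mad = np.median(np.abs(logp - med), axis=0) * 1.4826
    z = (logp - med) / np.maximum(mad, 1e-12)
    stat = np.mean(z**2, axis=1)
    smed = np.median(stat)
    smad = np.median(np.abs(stat - smed)) * 1.4826
    dev = np.abs(stat - smed) / np.maximum(smad, 1e-12)
    bad = [epochs.channel_labels[i] for i in np.where(dev > threshold_sd)[0]]
    if len(bad) == epochs.n_channels:
        raise ValueError("all channels flagged as bad; data are degenerate")
    return ChannelQCReport(
        bad_channels=bad, per_channel_statistic=stat, threshold_sd=threshold_sd
    )


def _spherical_spline_matrix(
    pos_good: np.ndarray, pos_bad: np.ndarray, order: int = 4, n_terms: int = 50,
    reg: float = 1e-5,
) -> np.ndarray:
    """Perrin-style spherical-spline interpolation operator (bad x good).

    g(cos) = 1/(4 pi) * sum_n (2n+1) / (n (n+1))^order * P_n(cos).  The
    spline coefficients (c, c0) solve the regularized bordered system
    [[G, 1], [1', 0]] [c; c0] = [z; 0]; the value at a bad electrode is
    Gb c + c0, which is linear in the good-channel data z, so a single
    interpolation matrix M with est = M z covers all time samples.
    """
    def gfun(cosang: np.ndarray) -> np.ndarray:
        out = np.zeros_like(cosang, dtype=np.float64)
        for n in range(1, n_terms + 1):
            out += (2 * n + 1) / (n * (n + 1)) ** order * legendre(n)(cosang)
        return out / (4.0 * np.pi)

    m = len(pos_good)
    cos_gg = np.clip(pos_good @ pos_good.T, -1.0, 1.0)
    cos_bg = np.clip(pos_bad @ pos_good.T, -1.0, 1.0)
    G = gfun(cos_gg) + reg * np.eye(m)
    Gb = gfun(cos_bg)
    C = np.zeros((m + 1, m + 1))
    C[:m, :m] = G
    C[m, :m] = 1.0
    C[:m, m] = 1.0
    lhs = np.hstack([Gb, np.ones((len(pos_bad), 1))])  # evaluate spline at bad sites
    M = lhs @ np.linalg.inv(C)
    return M[:, :m]


def interpolate_channels(epochs: EpochArray, bad: list[str]) -> EpochArray:
    """Replace bad channels by spherical-spline estimates from good channels."""
    if not bad:
        return epochs.copy_with(data=epochs.data.copy())
    idx_bad = [epochs.channel_index(b) for b in bad]
    idx_good = [i for i in range(epochs.n_channels) if i not in idx_bad]
    if len(idx_good) < 4:
        raise ValueError("need at least 4 good channels for spline interpolation")
    pos = epochs.channel_positions
    if not np.all(np.isfinite(pos[idx_bad])):
        raise ValueError("bad channels lack positions")
    M = _spherical_spline_matrix(pos[idx_good], pos[idx_bad])
    data = epochs.data.copy()
    data[:, idx_bad, :] = np.einsum("bg,tgs->tbs", M, data[:, idx_good, :])
    return epochs.copy_with(data=data)


def reject_amplitude_artifacts(epochs: EpochArray, peak_to_peak_uv: float = 150.0) -> EpochArray:
    """Flag trials whose peak-to-peak amplitude on any channel exceeds the
    threshold (per-channel criterion, the stricter reading)."""
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    bad = np.any(ptp > peak_to_peak_uv, axis=1)
    meta = epochs.trial_meta.copy()
    meta["keep_flag"] = meta["keep_flag"].to_numpy(dtype=bool) & ~bad
    return epochs.copy_with(trial_meta=meta)


def flag_muscle_artifacts(epochs: EpochArray, z_threshold: float = 4.0) -> EpochArray:
    """Flag trials with outlying high-frequency (>30 Hz) power.

    Per trial, power above 30 Hz is summed over channels; trials whose
    log-power z-score across trials exceeds ``z_threshold`` are flagged.  At
    sampling rates of 60 Hz or less the band is empty and the data are
    returned unchanged.
    """
    sf = epochs.sfreq
    if sf / 2 <= 30.0:
        return epochs
    f, pxx = sps.welch(epochs.data, fs=sf, nperseg=min(epochs.data.shape[-1], int(sf)), axis=-1)
    hf = f > 30.0
    power = np.log10(np.maximum(pxx[..., hf].sum(axis=(1, 2)), 1e-300))
    z = (power - power.mean()) / max(power.std(), 1e-12)
    meta = epochs.trial_meta.copy()
    meta["keep_flag"] = meta["keep_flag"].to_numpy(dtype=bool) & ~(z > z_threshold)
    return epochs.copy_with(trial_meta=meta)


def _pad_filtfilt(data: np.ndarray, sos: np.ndarray, sfreq: float, pad_s: float = 1.0) -> np.ndarray:
    """Zero-phase filtering with reflect padding along the last axis.

    Epochs are short relative to the 0.1 Hz high-pass, so each edge is
    extended by ``pad_s`` seconds of (possibly repeated) reflection before
    forward-backward filtering.
    """
    n = data.shape[-1]
    pad = min(int(round(pad_s * sfreq)), 10 * n)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sps.sosfiltfilt(sos, padded, axis=-1, padlen=0)
    return out[..., pad : pad + n]


def bandpass_filter(
    epochs: EpochArray, low_hz: float = 0.1, high_hz: float = 30.0, order: int = 4
) -> EpochArray:
    """Zero-phase Butterworth band-pass (forward-backward; zero group delay)."""
    nyq = epochs.sfreq / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"invalid band {low_hz}-{high_hz} Hz for Nyquist {nyq} Hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=epochs.sfreq, output="sos")
    return epochs.copy_with(data=_pad_filtfilt(epochs.data, sos, epochs.sfreq))


def lowpass_filter(epochs: EpochArray, high_hz: float = 100.0, order: int = 4) -> EpochArray:
    """Zero-phase Butterworth low-pass; no-op when the band edge is at or
    above Nyquist (e.g. on reduced-rate synthetic data)."""
    if high_hz >= epochs.sfreq / 2.0:
        return epochs
    sos = sps.butter(order, high_hz, btype="lowpass", fs=epochs.sfreq, output="sos")
    return epochs.copy_with(data=_pad_filtfilt(epochs.data, sos, epochs.sfreq))


def baseline_correct(
    epochs: EpochArray, window_ms: tuple[float, float] = (-100.0, 0.0)
) -> EpochArray:
    """Subtract the mean over the baseline window per trial and channel."""
    mask = (epochs.times >= window_ms[0]) & (epochs.times <= window_ms[1])
    if not np.any(mask):
        raise ValueError(f"baseline window {window_ms} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def rereference(
    epochs: EpochArray, reference_labels: tuple[str, ...] = ("TP9", "TP10")
) -> EpochArray:
    """Subtract the average of the reference channels from every channel."""
    idx = [epochs.channel_index(lb) for lb in reference_labels]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(
        data=epochs.data - ref, reference="+".join(reference_labels)
    )


def preprocess(
    epochs: EpochArray,
    bad_channel_threshold_sd: float = 4.0,
    peak_to_peak_uv: float = 150.0,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    filter_order: int = 4,
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    reference_labels: tuple[str, ...] = ("TP9", "TP10"),
    prefilter_lowpass_hz: float | None = 100.0,
    muscle_z_threshold: float | None = 4.0,
) -> tuple[EpochArray, dict]:
    """Run the full cleaning chain; returns (epochs, QC report dict)."""
    qc = detect_bad_channels(epochs, bad_channel_threshold_sd)
    out = interpolate_channels(epochs, qc.bad_channels)
    if prefilter_lowpass_hz is not None:
        out = lowpass_filter(out, prefilter_lowpass_hz)
    if muscle_z_threshold is not None:
        out = flag_muscle_artifacts(out, muscle_z_threshold)
    out = reject_amplitude_artifacts(out, peak_to_peak_uv)
    n_rej = int((~out.trial_meta["keep_flag"]).sum())
    out = bandpass_filter(out, low_hz, high_hz, filter_order)
    out = baseline_correct(out, baseline_ms)
    out = rereference(out, reference_labels)
    report = {
        "bad_channels": qc.bad_channels,
        "n_channels_interpolated": len(qc.bad_channels),
        "n_trials": int(epochs.n_trials),
        "n_trials_rejected": n_rej,
        "pct_trials_rejected": 100.0 * n_rej / max(epochs.n_trials, 1),
        "reference": "+".join(reference_labels),
        "band_hz": [low_hz, high_hz],
        "peak_to_peak_uv": peak_to_peak_uv,
    }
    return out, report
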