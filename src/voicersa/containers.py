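"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of objects between stages: epoched EEG
(trials x channels x time with per-trial metadata), single representational
dissimilarity matrices (RDMs), and time-resolved series of neural RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

__all__ = ["EpochArray", "RDM", "NeuralRDMSeries"]

#: trial_meta columns required by every stage
TRIAL_META_COLUMNS = ("stimulus_id", "trial_type", "keep_flag")


@dataclass
class EpochArray:
    """Epoched EEG: ``data`` is trials x channels x time in microvolts.

    ``times`` is in milliseconds relative to stimulus onset on a uniform
    grid.  ``trial_meta`` carries at least ``stimulus_id`` (which voice
    recording was played), ``trial_type`` (``experimental`` or a vigilance
    category) and ``keep_flag`` (set to False by artifact rejection; data are
    never deleted, only flagged).  ``channel_positions`` are unit-sphere
    coordinates used for spherical-spline interpolation.
    """

    data: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    channel_positions: np.ndarray
    trial_meta: pd.DataFrame
    reference: str = "common"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_trials, n_ch, n_times = self.data.shape
        if len(self.times) != n_times:
            raise ValueError("times length mismatch")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing on a uniform grid")
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel label count mismatch")
        self.channel_positions = np.asarray(self.channel_positions, dtype=np.float64)
        if self.channel_positions.shape != (n_ch, 3):
            raise ValueError("channel_positions must be channels x 3")
        if len(self.trial_meta) != n_trials:
            raise ValueError("trial_meta length must equal trial count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        missing = [c for c in TRIAL_META_COLUMNS if c not in self.trial_meta.columns]
        if missing:
            raise ValueError(f"trial_meta missing columns: {missing}")
        self.trial_meta = self.trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def sfreq(self) -> float:
        """Sampling frequency in Hz implied by the millisecond time grid."""
        return 1000.0 / float(self.times[1] - self.times[0])

    def copy_with(self, **kw) -> "EpochArray":
        out = replace(self, **kw)
        return out

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def retained(self, trial_type: str | None = "experimental") -> "EpochArray":
        """Subset to trials with keep_flag set (optionally one trial_type)."""
        mask = self.trial_meta["keep_flag"].to_numpy(dtype=bool)
        if trial_type is not None:
            mask = mask & (self.trial_meta["trial_type"] == trial_type).to_numpy()
        return self.copy_with(
            data=self.data[mask], trial_meta=self.trial_meta.loc[mask].reset_index(drop=True)
        )


@dataclass
class RDM:
    """A single symmetric item x item dissimilarity matrix with zero/NaN diagonal.

    ``kind`` records the dissimilarity measure (``abs_rating_diff``,
    ``cosine_ltas``, ``abs_pc_diff``, ``decoding_accuracy``); ``name`` labels
    the source (e.g. a rated characteristic or a principal component).
    """

    values: np.ndarray
    items: list[str]
    kind: str
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ValueError("RDM shape must match item count")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.values[off], self.values.T[off], equal_nan=True):
            raise ValueError("RDM must be symmetric")

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass
class NeuralRDMSeries:
    """Time-resolved neural RDM: ``values`` is time x item x item decoding
    accuracy in [0, 1]; the diagonal is stored as NaN and excluded from every
    summary."""

    values: np.ndarray
    times: np.ndarray
    items: list[str]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        n = len(self.items)
        if self.values.ndim != 3 or self.values.shape[1:] != (n, n):
            raise ValueError("values must be time x item x item")
        if self.values.shape[0] != len(self.times):
            raise ValueError("time axis mismatch")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def at_time(self, time_ms: float) -> RDM:
        idx = int(np.argmin(np.abs(self.times - time_ms)))
        return RDM(
            values=self.values[idx],
            items=list(self.items),
            kind="decoding_accuracy",
            name=f"t={self.times[idx]:g}ms",
        )
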