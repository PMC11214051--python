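"""File formats: epoch containers, RDM archives, tables and WAV.

Array containers (epochs, RDM series) are HDF5 files with named datasets and
attributes; round trips are bit-exact for float64 data.  Tables (ratings,
acoustic features, time courses) are plain CSV with schema validation on
read.  WAV files are PCM mono read through scipy.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochArray, NeuralRDMSeries, RDM

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_rdm_series",
    "load_rdm_series",
    "save_rdm",
    "load_rdm",
    "read_ratings_csv",
    "write_ratings_csv",
    "read_features_csv",
    "read_wav",
    "write_timecourses_csv",
    "read_timecourses_csv",
]


def _write_strings(grp: h5py.Group, name: str, values: list[str]) -> None:
    grp.create_dataset(name, data=np.array([v.encode("utf-8") for v in values]))


def _read_strings(grp: h5py.Group, name: str) -> list[str]:
    return [v.decode("utf-8") for v in grp[name][()]]


def save_epochs(path: str | Path, epochs: EpochArray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channel_positions", data=epochs.channel_positions)
        _write_strings(f, "channel_labels", epochs.channel_labels)
        meta = f.create_group("trial_meta")
        for col in epochs.trial_meta.columns:
            vals = epochs.trial_meta[col]
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                _write_strings(meta, col, [str(v) for v in vals])
            else:
                meta.create_dataset(col, data=vals.to_numpy())
        f.attrs["reference"] = epochs.reference
        f.attrs["container"] = "voicersa-epochs-v1"


def load_epochs(path: str | Path) -> EpochArray:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "voicersa-epochs-v1":
            raise ValueError(f"{path}: not a voicersa epoch container")
        meta = {}
        for col, ds in f["trial_meta"].items():
            vals = ds[()]
            if vals.dtype.kind in ("S", "O"):
                meta[col] = [v.decode("utf-8") for v in vals]
            else:
                meta[col] = vals
        return EpochArray(
            data=f["data"][()],
            times=f["times"][()],
            channel_labels=_read_strings(f, "channel_labels"),
            channel_positions=f["channel_positions"][()],
            trial_meta=pd.DataFrame(meta),
            reference=str(f.attrs["reference"]),
        )


def save_rdm_series(
    path: str | Path, series: NeuralRDMSeries, config_echo: dict | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=series.values)
        f.create_dataset("times", data=series.times)
        _write_strings(f, "items", series.items)
        f.attrs["participant_id"] = series.participant_id
        f.attrs["dissimilarity_kind"] = "decoding_accuracy"
        f.attrs["config"] = json.dumps(config_echo or {}, sort_keys=True)
        f.attrs["container"] = "voicersa-rdm-series-v1"


def load_rdm_series(path: str | Path) -> NeuralRDMSeries:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "voicersa-rdm-series-v1":
            raise ValueError(f"{path}: not a voicersa RDM series archive")
        return NeuralRDMSeries(
            values=f["values"][()],
            times=f["times"][()],
            items=_read_strings(f, "items"),
            participant_id=str(f.attrs["participant_id"]),
        )


def save_rdm(path: str | Path, rdm: RDM) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rdm.values)
        _write_strings(f, "items", rdm.items)
        f.attrs["dissimilarity_kind"] = rdm.kind
        f.attrs["name"] = rdm.name
        f.attrs["container"] = "voicersa-rdm-v1"


def load_rdm(path: str | Path) -> RDM:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "voicersa-rdm-v1":
            raise ValueError(f"{path}: not a voicersa RDM archive")
        return RDM(
            values=f["values"][()],
            items=_read_strings(f, "items"),
            kind=str(f.attrs["dissimilarity_kind"]),
            name=str(f.attrs["name"]),
        )


def write_ratings_csv(path: str | Path, ratings: pd.DataFrame) -> None:
    ratings.to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["rater_id", "stimulus_id", "characteristic", "rating"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ratings CSV missing columns {missing}")
    bad = df[(df["rating"] < 1) | (df["rating"] > 9) | (df["rating"] % 1 != 0)]
    if len(bad):
        raise ValueError(
            f"{path}: ratings must be integers in [1, 9]; "
            f"first offending rows:\n{bad.head()}"
        )
    df["rating"] = df["rating"].astype(int)
    return df


def read_features_csv(path: str | Path) -> pd.DataFrame:
    from .synthetic import ACOUSTIC_MEASURES

    df = pd.read_csv(path)
    missing = [c for c in ("stimulus_id", *ACOUSTIC_MEASURES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: acoustic feature CSV missing columns {missing}")
    return df


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """PCM mono waveform as float64 in [-1, 1] plus its sampling rate."""
    from scipy.io import wavfile

    sfreq, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(np.float64), float(sfreq)


def write_ltas_csv(path: str | Path, ltas) -> None:
    """LTAS matrix as CSV: stimulus_id column plus one column per frequency
    bin (linear power, header = bin center in Hz)."""
    df = pd.DataFrame(ltas.to_linear(), columns=[f"{f:g}" for f in ltas.freqs])
    df.insert(0, "stimulus_id", ltas.items)
    df.to_csv(path, index=False)


def read_ltas_csv(path: str | Path):
    from .acoustic import LTASMatrix

    df = pd.read_csv(path)
    if "stimulus_id" not in df.columns:
        raise ValueError(f"{path}: LTAS CSV missing stimulus_id column")
    freqs = np.array([float(c) for c in df.columns if c != "stimulus_id"])
    bin_hz = float(np.median(np.diff(freqs))) if len(freqs) > 1 else float(freqs[0])
    return LTASMatrix(
        spectra=df.drop(columns="stimulus_id").to_numpy(dtype=np.float64),
        freqs=freqs,
        bin_hz=bin_hz,
        fmax=float(freqs[-1] + bin_hz / 2),
        items=list(df["stimulus_id"]),
        domain="linear",
    )


def write_timecourses_csv(path: str | Path, courses: dict) -> None:
    """Long-format table: participant, characteristic, model, time_ms, rho."""
    rows = []
    for (char, model), tc in courses.items():
        for p, pid in enumerate(tc.participant_ids):
            for t, time_ms in enumerate(tc.times):
                rows.append((pid, char, model, float(time_ms), float(tc.rho[p, t])))
    pd.DataFrame(
        rows, columns=["participant", "characteristic", "model", "time_ms", "rho"]
    ).to_csv(path, index=False)


def read_timecourses_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["participant", "characteristic", "model", "time_ms", "rho"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: time-course CSV missing columns {missing}")
    return df
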