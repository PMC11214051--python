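"""Synthetic voice-rating / EEG experiment with known ground truth.

The generator emulates the structure of a voice person-perception EEG study:
32 speakers each recorded producing three vowels (/a/, /i/, /u/) gives 96
stimuli; listeners rate the voices on nine person-characteristic scales
(1-9); EEG is recorded while participants hear 40 repetitions of each
stimulus plus interspersed vigilance probe trials.

Everything downstream of the generator (preprocessing, decoding, RSA,
cluster inference) can therefore be tested against an embedded ground truth:

* a low-dimensional latent "trait space" per speaker drives the ratings of
  the eight analyzable characteristics through a loading matrix (this is
  what produces the strong intercorrelation of valenced traits seen in real
  rating data — the halo effect);
* the same latent scores drive spatiotemporal EEG signal inside
  per-dimension effect windows, through fixed scalp patterns;
* acoustic features and long-term average spectra (LTAS) are generated with
  a controllable mixing of the latent dimensions, so acoustic confounding of
  the rating-EEG relation can be switched on and off.

Scales: the full design (96 stimuli x 40 repetitions, 1 kHz) is available,
but the default "desk" scale used throughout the tests is 16 stimuli
(8 speakers x 2 vowels), 20 repetitions and a 10-ms grid.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EpochArray

__all__ = [
    "CHARACTERISTICS",
    "LOW_AGREEMENT_CHARACTERISTIC",
    "StimulusSet",
    "TrialRecord",
    "ExperimentDesign",
    "LatentPersonSpace",
    "SyntheticTruth",
    "make_stimulus_set",
    "generate_design",
    "generate_latent_space",
    "generate_ratings",
    "generate_acoustics",
    "generate_eeg",
    "standard_montage",
]

#: the eight person characteristics retained for analysis
CHARACTERISTICS = (
    "gender",
    "age",
    "health",
    "attractiveness",
    "dominance",
    "trustworthiness",
    "educatedness",
    "professionalism",
)
#: ninth rated scale, generated with poor inter-rater agreement and dropped
#: by the behavioral screening stage
LOW_AGREEMENT_CHARACTERISTIC = "sexual_orientation"

VOWELS = ("a", "i", "u")

#: 13 perceptually salient acoustic measures (order is the canonical column order)
ACOUSTIC_MEASURES = (
    "F0_mean",
    "F1",
    "F2",
    "F3",
    "F4",
    "DF",
    "H1H2",
    "H2H4",
    "H4H2k",
    "H2kH5k",
    "CPP",
    "Energy",
    "HNR",
)


# ---------------------------------------------------------------------------
# stimuli and experiment design
# ---------------------------------------------------------------------------


@dataclass
class StimulusSet:
    """The stimulus inventory: one row per recording (speaker x vowel)."""

    table: pd.DataFrame  # stimulus_id, speaker_id, vowel, speaker_gender, speaker_age_group

    def __post_init__(self) -> None:
        t = self.table
        per_speaker = t.groupby("speaker_id")["vowel"].nunique()
        n_vowels = t["vowel"].nunique()
        if not (per_speaker == n_vowels).all():
            raise ValueError("every speaker must contribute one recording per vowel")
        genders = t.drop_duplicates("speaker_id")["speaker_gender"].value_counts()
        if len(genders) == 2 and genders.iloc[0] != genders.iloc[1]:
            raise ValueError("speaker genders must be balanced")
        ages = t.drop_duplicates("speaker_id")["speaker_age_group"].value_counts()
        if len(ages) == 2 and ages.iloc[0] != ages.iloc[1]:
            raise ValueError("speaker age groups must be balanced")

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.table["stimulus_id"])

    @property
    def speaker_ids(self) -> list[str]:
        return list(self.table["speaker_id"].unique())

    @property
    def n_stimuli(self) -> int:
        return len(self.table)

    @property
    def n_speakers(self) -> int:
        return self.table["speaker_id"].nunique()

    def speaker_of(self) -> pd.Series:
        return self.table.set_index("stimulus_id")["speaker_id"]


def make_stimulus_set(n_speakers: int = 32, vowels: Sequence[str] = VOWELS) -> StimulusSet:
    """Build a balanced stimulus set: ``n_speakers`` x ``len(vowels)`` recordings.

    Speakers alternate gender and are split half/half into young/old age
    groups; ``n_speakers`` must be a multiple of 4 to keep both balances.
    """
    if n_speakers % 4:
        raise ValueError("n_speakers must be a multiple of 4 for gender/age balance")
    rows = []
    for s in range(n_speakers):
        speaker = f"s{s + 1:02d}"
        gender = "female" if s % 2 == 0 else "male"
        age = "young" if (s // 2) % 2 == 0 else "old"
        for v in vowels:
            rows.append(
                {
                    "stimulus_id": f"{speaker}_{v}",
                    "speaker_id": speaker,
                    "vowel": v,
                    "speaker_gender": gender,
                    "speaker_age_group": age,
                }
            )
    return StimulusSet(pd.DataFrame(rows))


@dataclass
class TrialRecord:
    index: int
    block: int
    stimulus_id: str
    trial_type: str  # experimental | vigilance_identical | vigilance_different
    onset_asynchrony_ms: float


@dataclass
class ExperimentDesign:
    trials: list[TrialRecord]
    n_blocks: int
    jitter_range_ms: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def n_experimental(self) -> int:
        return sum(t.trial_type == "experimental" for t in self.trials)

    def n_vigilance(self) -> int:
        return sum(t.trial_type != "experimental" for t in self.trials)

    def vigilance_presentations(self) -> int:
        """Presentations of vigilance stimuli: identical-pair probes present
        the vigilance stimulus twice, different-pair probes once."""
        n = 0
        for t in self.trials:
            if t.trial_type == "vigilance_identical":
                n += 2
            elif t.trial_type == "vigilance_different":
                n += 1
        return n


def generate_design(
    stimuli: StimulusSet,
    n_repetitions: int,
    vigilance_stimuli: int = 0,
    vigilance_repetitions: int = 0,
    n_blocks: int = 1,
    seed: int = 0,
    jitter_range_ms: tuple[float, float] = (800.0, 1000.0),
) -> ExperimentDesign:
    """Randomized trial sequence: experimental trials plus vigilance probes.

    Experimental trials number ``n_stimuli x n_repetitions``; vigilance
    probes number ``vigilance_stimuli x vigilance_repetitions`` and are split
    50/50 into identical-pair and different-pair probes.  Both counts must
    divide evenly over ``n_blocks``.  Within each block, vigilance probes are
    assigned one per equal-length segment at a random non-initial position,
    which guarantees they are never the first trial of a block and never
    consecutive.
    """
    if n_repetitions < 1 or n_blocks < 1:
        raise ValueError("counts must be positive")
    n_exp = stimuli.n_stimuli * n_repetitions
    n_vig = vigilance_stimuli * vigilance_repetitions
    if n_exp % n_blocks or n_vig % n_blocks:
        raise ValueError(
            f"cannot split {n_exp} experimental + {n_vig} vigilance trials "
            f"evenly over {n_blocks} blocks"
        )
    rng = np.random.default_rng(seed)
    exp_per_block = n_exp // n_blocks
    vig_per_block = n_vig // n_blocks
    per_block = exp_per_block + vig_per_block
    if vig_per_block:
        seg = per_block // vig_per_block
        if seg < 2:
            raise ValueError(
                f"insufficient slots to space {vig_per_block} vigilance trials "
                f"in a {per_block}-trial block"
            )

    # balanced experimental sequence, shuffled globally
    exp_ids = np.repeat(np.asarray(stimuli.stimulus_ids, dtype=object), n_repetitions)
    rng.shuffle(exp_ids)

    # vigilance probes: per stimulus, half identical / half different
    vig_records: list[tuple[str, str]] = []
    for v in range(vigilance_stimuli):
        vid = f"vig{v + 1:02d}"
        n_ident = vigilance_repetitions // 2 + (
            int(rng.integers(2)) if vigilance_repetitions % 2 else 0
        )
        kinds = ["vigilance_identical"] * n_ident + ["vigilance_different"] * (
            vigilance_repetitions - n_ident
        )
        vig_records.extend((vid, k) for k in kinds)
    vig_arr = np.array(vig_records, dtype=object).reshape(-1, 2)
    if len(vig_arr):
        rng.shuffle(vig_arr)

    trials: list[TrialRecord] = []
    e_ptr = v_ptr = 0
    idx = 0
    for b in range(n_blocks):
        slots: list[tuple[str, str]] = [("", "experimental")] * per_block
        if vig_per_block:
            seg = per_block // vig_per_block
            for k in range(vig_per_block):
                pos = k * seg + int(rng.integers(1, seg))  # never segment-initial
                vid, kind = vig_arr[v_ptr]
                v_ptr += 1
                slots[pos] = (vid, kind)
        for sid, kind in slots:
            if kind == "experimental":
                sid = exp_ids[e_ptr]
                e_ptr += 1
            trials.append(
                TrialRecord(
                    index=idx,
                    block=b,
                    stimulus_id=str(sid),
                    trial_type=kind,
                    onset_asynchrony_ms=float(rng.uniform(*jitter_range_ms)),
                )
            )
            idx += 1
    return ExperimentDesign(trials=trials, n_blocks=n_blocks, jitter_range_ms=jitter_range_ms)


# ---------------------------------------------------------------------------
# latent trait space and ratings
# ---------------------------------------------------------------------------


@dataclass
class LatentPersonSpace:
    """Speaker-level latent trait space driving ratings, acoustics and EEG.

    ``latent_scores`` (speakers x n_latent) are exactly standardized;
    characteristic values are ``loading_matrix.T @ latent + uniqueness * eps``
    so the implied characteristic correlation matrix is available in closed
    form.
    """

    latent_scores: np.ndarray  # speakers x n_latent
    loading_matrix: np.ndarray  # n_latent x n_characteristics
    uniqueness: np.ndarray  # per-characteristic residual SD
    characteristics: tuple[str, ...] = CHARACTERISTICS
    speaker_ids: list[str] = field(default_factory=list)

    @property
    def n_latent(self) -> int:
        return self.latent_scores.shape[1]

    def implied_covariance(self) -> np.ndarray:
        return self.loading_matrix.T @ self.loading_matrix + np.diag(self.uniqueness**2)

    def implied_correlations(self) -> np.ndarray:
        """Closed-form characteristic correlation matrix under the model."""
        cov = self.implied_covariance()
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def characteristic_values(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Speaker x characteristic values; residuals drawn from ``rng`` if given."""
        vals = self.latent_scores @ self.loading_matrix
        if rng is not None and np.any(self.uniqueness > 0):
            vals = vals + rng.standard_normal(vals.shape) * self.uniqueness
        return vals


def generate_latent_space(
    n_speakers: int,
    n_latent: int,
    loading_spec: np.ndarray,
    seed: int = 0,
    uniqueness: np.ndarray | None = None,
    characteristics: Sequence[str] = CHARACTERISTICS,
) -> LatentPersonSpace:
    """Draw standardized latent scores under a confirmatory loading structure.

    ``loading_spec`` is n_latent x n_characteristics.  If ``uniqueness`` is
    omitted it is chosen so each characteristic has unit total variance
    (requires column loadings with sum of squares <= 1).
    """
    loading_spec = np.atleast_2d(np.asarray(loading_spec, dtype=np.float64))
    if loading_spec.shape != (n_latent, len(characteristics)):
        raise ValueError(
            f"loading_spec must be {n_latent} x {len(characteristics)}, "
            f"got {loading_spec.shape}"
        )
    comm = np.sum(loading_spec**2, axis=0)
    if uniqueness is None:
        if np.any(comm > 1 + 1e-9):
            raise ValueError("column communalities exceed 1; pass uniqueness explicitly")
        uniqueness = np.sqrt(np.clip(1.0 - comm, 0.0, None))
    else:
        uniqueness = np.asarray(uniqueness, dtype=np.float64)
    cov = loading_spec.T @ loading_spec + np.diag(uniqueness**2)
    if np.any(np.diag(cov) <= 0):
        raise ValueError("implied characteristic variance must be positive")
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
        raise ValueError("loading_spec implies a non-PSD correlation matrix")

    rng = np.random.default_rng([seed, 11])
    z = rng.standard_normal((n_speakers, n_latent))
    if n_speakers > 1:
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    return LatentPersonSpace(
        latent_scores=z,
        loading_matrix=loading_spec,
        uniqueness=uniqueness,
        characteristics=tuple(characteristics),
        speaker_ids=[f"s{i + 1:02d}" for i in range(n_speakers)],
    )


def default_loading_spec(n_latent: int = 2) -> np.ndarray:
    """A two-dimensional trait space emulating the halo structure of voice
    ratings: valenced traits (trustworthiness, dominance, health,
    educatedness, professionalism) load on latent 1; physical
    characteristics (gender, attractiveness, and more weakly age) load on
    latent 2."""
    spec = np.zeros((n_latent, len(CHARACTERISTICS)))
    idx = {c: i for i, c in enumerate(CHARACTERISTICS)}
    for c in ("trustworthiness", "dominance", "health", "educatedness", "professionalism"):
        spec[0, idx[c]] = 0.85
    for c, w in (("gender", 0.9), ("attractiveness", 0.8), ("age", 0.55)):
        if n_latent > 1:
            spec[1, idx[c]] = w
        else:
            spec[0, idx[c]] = w
    return spec


def generate_ratings(
    space: LatentPersonSpace,
    stimuli: StimulusSet,
    n_raters: int = 20,
    rater_noise_sd: float = 1.0,
    seed: int = 0,
    stimulus_jitter_sd: float = 0.2,
    scale_mean: float = 5.0,
    scale_sd: float = 1.5,
    include_low_agreement_scale: bool = True,
) -> pd.DataFrame:
    """Integer 1-9 ratings: tidy frame (rater_id, stimulus_id, characteristic, rating).

    Per stimulus, the latent-driven characteristic value of its speaker gets
    independent stimulus-level jitter (the three vowels of a speaker share
    the speaker latent but are not rated identically), is mapped affinely to
    the 1-9 scale (mean 5, SD 1.5), perturbed per rater by Gaussian noise,
    rounded and clipped.  The ninth scale (sexual orientation) carries no
    latent signal and heavy rater noise, emulating a scale that fails the
    inter-rater agreement screen.
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng([seed, 23])
    spk = stimuli.table["speaker_id"].map(
        {s: i for i, s in enumerate(stimuli.speaker_ids)}
    ).to_numpy()
    char_vals = space.characteristic_values(rng)  # speakers x 8
    stim_vals = char_vals[spk] + rng.standard_normal(
        (stimuli.n_stimuli, len(space.characteristics))
    ) * stimulus_jitter_sd
    chars = list(space.characteristics)
    values = stim_vals
    noise_sds = np.full(len(chars), rater_noise_sd)
    if include_low_agreement_scale:
        chars = chars + [LOW_AGREEMENT_CHARACTERISTIC]
        base = rng.standard_normal((stimuli.n_stimuli, 1)) * 0.3
        values = np.hstack([stim_vals, base])
        noise_sds = np.append(noise_sds, 3.0)

    rows = []
    sids = stimuli.stimulus_ids
    for r in range(n_raters):
        noisy = values + rng.standard_normal(values.shape) * noise_sds
        scaled = np.clip(np.rint(scale_mean + scale_sd * noisy), 1, 9).astype(int)
        for j, c in enumerate(chars):
            for i, sid in enumerate(sids):
                rows.append((f"r{r + 1:02d}", sid, c, scaled[i, j]))
    return pd.DataFrame(rows, columns=["rater_id", "stimulus_id", "characteristic", "rating"])


# ---------------------------------------------------------------------------
# acoustics
# ---------------------------------------------------------------------------

# base value and spread of each acoustic measure (plausible adult-voice ranges)
_ACOUSTIC_BASE = {
    "F0_mean": (165.0, 40.0),
    "H1H2": (4.0, 3.0),
    "H2H4": (3.0, 3.0),
    "H4H2k": (8.0, 4.0),
    "H2kH5k": (10.0, 4.0),
    "CPP": (20.0, 4.0),
    "Energy": (0.01, 0.004),
    "HNR": (18.0, 4.0),
}
# vowel formant targets (Hz)
_VOWEL_FORMANTS = {
    "a": (800.0, 1200.0, 2600.0, 3600.0),
    "i": (300.0, 2300.0, 3000.0, 3800.0),
    "u": (320.0, 800.0, 2300.0, 3400.0),
    "e": (450.0, 1900.0, 2700.0, 3700.0),
    "o": (450.0, 900.0, 2500.0, 3500.0),
}


def default_acoustic_mixing(n_latent: int) -> np.ndarray:
    """13 x n_latent mixing of latent dimensions into acoustic measures.

    Latent 2 (the physical gender/attractiveness dimension when the default
    loading spec is used) shifts F0 and shortens the vocal tract (higher
    formants); latent 1 modestly shifts voice-quality measures.  Mirrors the
    empirical situation where perceived characteristics co-vary with
    measurable acoustics.
    """
    m = np.zeros((len(ACOUSTIC_MEASURES), n_latent))
    col = {name: i for i, name in enumerate(ACOUSTIC_MEASURES)}
    phys = 1 if n_latent > 1 else 0
    m[col["F0_mean"], phys] = 0.8
    for f in ("F1", "F2", "F3", "F4", "DF"):
        m[col[f], phys] = 0.5
    for q in ("H1H2", "CPP", "HNR"):
        m[col[q], 0] = 0.4
    return m


def generate_acoustics(
    space: LatentPersonSpace,
    stimuli: StimulusSet,
    seed: int = 0,
    mixing: np.ndarray | None = None,
    noise_sd: float = 0.5,
    ltas_bin_hz: float = 100.0,
    ltas_fmax: float = 8000.0,
) -> tuple[pd.DataFrame, "LTASMatrix"]:
    """Acoustic feature table (13 measures per stimulus) and LTAS matrix.

    ``mixing`` (13 x n_latent) states how strongly each measure tracks each
    latent dimension, in within-measure SD units; zero mixing gives
    acoustics independent of the trait space.  Formants are generated from
    vowel targets scaled by a speaker vocal-tract factor, and formant
    dispersion (DF) is computed from them with the regression formula, so
    the table is internally consistent.  The LTAS is a parametric spectrum:
    a speaker-specific spectral tilt plus Gaussian formant bumps, in linear
    power up to ``ltas_fmax``.
    """
    from .acoustic import LTASMatrix, formant_dispersion

    rng = np.random.default_rng([seed, 37])
    if mixing is None:
        mixing = default_acoustic_mixing(space.n_latent)
    mixing = np.asarray(mixing, dtype=np.float64)
    if mixing.shape != (len(ACOUSTIC_MEASURES), space.n_latent):
        raise ValueError("mixing must be 13 x n_latent")

    spk_index = {s: i for i, s in enumerate(stimuli.speaker_ids)}
    n_stim = stimuli.n_stimuli
    latent_per_stim = space.latent_scores[
        [spk_index[s] for s in stimuli.table["speaker_id"]]
    ]  # stim x n_latent
    drive = latent_per_stim @ mixing.T  # stim x 13 (in SD units)
    eps = rng.standard_normal((n_stim, len(ACOUSTIC_MEASURES))) * noise_sd

    # vocal-tract length factor: shorter tract -> higher formants
    vt = 1.0 + 0.08 * (drive[:, ACOUSTIC_MEASURES.index("F1")] + eps[:, ACOUSTIC_MEASURES.index("F1")])
    rows = {}
    vowels = stimuli.table["vowel"].to_numpy()
    formants = np.array([_VOWEL_FORMANTS[v] for v in vowels]) * vt[:, None]
    for k, name in enumerate(("F1", "F2", "F3", "F4")):
        rows[name] = formants[:, k]
    rows["DF"] = np.array([formant_dispersion(f) for f in formants])
    for name, (base, sd) in _ACOUSTIC_BASE.items():
        j = ACOUSTIC_MEASURES.index(name)
        rows[name] = base + sd * (drive[:, j] + eps[:, j])
    rows["F0_mean"] = np.maximum(rows["F0_mean"], 60.0)
    rows["Energy"] = np.maximum(rows["Energy"], 1e-4)
    features = pd.DataFrame({"stimulus_id": stimuli.stimulus_ids})
    for name in ACOUSTIC_MEASURES:
        features[name] = rows[name]

    # parametric LTAS: tilt + formant bumps, linear power
    freqs = np.arange(ltas_bin_hz / 2, ltas_fmax, ltas_bin_hz)
    tilt = 1.1 + 0.15 * latent_per_stim[:, 0] if space.n_latent else np.full(n_stim, 1.1)
    spectra = np.empty((n_stim, len(freqs)))
    speaker_rough = rng.standard_normal((stimuli.n_speakers, len(freqs))) * 0.05
    for i in range(n_stim):
        base = (1.0 + freqs / 500.0) ** (-tilt[i])
        bumps = np.zeros_like(freqs)
        for fk in formants[i]:
            bumps += 0.8 * np.exp(-0.5 * ((freqs - fk) / 150.0) ** 2)
        rough = speaker_rough[spk_index[stimuli.table["speaker_id"].iloc[i]]]
        spectra[i] = base * (1.0 + bumps) * np.exp(rough)
    ltas = LTASMatrix(
        spectra=spectra,
        freqs=freqs,
        bin_hz=ltas_bin_hz,
        fmax=ltas_fmax,
        items=stimuli.stimulus_ids,
        domain="linear",
    )
    return features, ltas


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

#: 32-channel 10-20 cap, ordered so any prefix keeps whole-scalp coverage and
#: always contains the TP9/TP10 reference channels
MONTAGE_32 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 T7 C3 Cz C4 T8 TP9 TP10 P7 P3 Pz P4 P8 O1 O2 "
    "FC5 FC1 FC2 FC6 CP5 CP1 CP2 CP6 PO9 Oz PO10"
).split()


def standard_montage(n_channels: int = 32) -> tuple[list[str], np.ndarray]:
    """Channel labels and unit-sphere positions from the standard 10-05 layout."""
    import mne

    if not 14 <= n_channels <= len(MONTAGE_32):
        raise ValueError(f"n_channels must be in [14, {len(MONTAGE_32)}]")
    labels = MONTAGE_32[:n_channels]
    try:
        mont = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older layout name
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    xyz = np.array([pos[lb] for lb in labels])
    xyz = xyz - xyz.mean(axis=0)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return labels, xyz


@dataclass
class SyntheticTruth:
    """Ground-truth description of the EEG signal to embed.

    ``effect_windows`` gives, per latent dimension, the (start, end) in ms
    where that dimension's scalp pattern is active (raised-cosine temporal
    envelope).  The optional acoustic confound adds, per acoustic driver
    dimension, stimulus-level scores times a scalp pattern inside
    ``acoustic_windows``.  ``snr`` is the amplitude of each signal component
    relative to the noise standard deviation; ``snr = 0`` yields pure noise.
    """

    effect_windows: tuple[tuple[float, float], ...]
    snr: float = 1.0
    seed: int = 0
    scalp_patterns: np.ndarray | None = None  # n_latent x channels
    acoustic_patterns: np.ndarray | None = None  # n_acoustic x channels
    acoustic_windows: tuple[tuple[float, float], ...] = ()
    acoustic_drivers: np.ndarray | None = None  # n_stimuli x n_acoustic
    acoustic_snr: float | None = None  # defaults to snr


def _raised_cosine(times: np.ndarray, start: float, end: float) -> np.ndarray:
    k = np.zeros_like(times)
    inside = (times >= start) & (times <= end)
    k[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (times[inside] - start) / (end - start)))
    return k


def _spatial_chol(positions: np.ndarray, neighbor_r: float = 0.6) -> np.ndarray:
    """Cholesky factor of an exponential spatial correlation: nearest
    neighbours correlate at ``neighbor_r``."""
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    nn = np.median(np.sort(d, axis=1)[:, 1])
    lam = -nn / np.log(neighbor_r)
    corr = np.exp(-d / lam)
    corr += 1e-6 * np.eye(len(positions))
    return np.linalg.cholesky(corr)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sfreq: float) -> np.ndarray:
    """Unit-variance noise with a 1/f-shaped spectrum along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    f = np.fft.rfftfreq(n, d=1.0 / sfreq)
    gain = np.ones_like(f)
    nz = f > 1.0  # flat below 1 Hz
    gain[nz] = 1.0 / np.sqrt(f[nz])
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_eeg(
    design: ExperimentDesign,
    space: LatentPersonSpace,
    truth: SyntheticTruth,
    stimuli: StimulusSet,
    n_channels: int = 32,
    sfreq: float = 1000.0,
    tmin_ms: float = -100.0,
    tmax_ms: float = 700.0,
    noise_sd_uv: float = 5.0,
    neighbor_r: float = 0.6,
    outlier_trial_rate: float = 0.0,
    participant_id: str = "p01",
) -> EpochArray:
    """Epoched EEG for every trial in ``design`` with embedded geometry.

    Each experimental trial is the deterministic stimulus response (latent
    scores x scalp patterns x raised-cosine windows, plus the optional
    acoustic-confound term) scaled to ``truth.snr`` times the noise SD, plus
    spatially correlated 1/f noise.  Trials of the same stimulus share the
    deterministic part exactly.  Vigilance trials contain noise only.  With
    ``outlier_trial_rate`` > 0, a fraction of trials receives a large
    transient (exceeding typical artifact-rejection thresholds).
    """
    times = np.arange(tmin_ms, tmax_ms + 0.5 * 1000.0 / sfreq, 1000.0 / sfreq)
    for w in list(truth.effect_windows) + list(truth.acoustic_windows):
        if w[0] < times[0] or w[1] > times[-1]:
            raise ValueError(f"effect window {w} outside epoch {times[0]}..{times[-1]} ms")
    labels, positions = standard_montage(n_channels)
    rng = np.random.default_rng([truth.seed, 53])

    n_latent = space.n_latent
    patterns = truth.scalp_patterns
    if patterns is None:
        patterns = rng.standard_normal((n_latent, n_channels))
        patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
    if len(truth.effect_windows) != n_latent:
        raise ValueError("need one effect window per latent dimension")

    spk_index = {s: i for i, s in enumerate(stimuli.speaker_ids)}
    stim_index = {s: i for i, s in enumerate(stimuli.stimulus_ids)}
    latent_stim = space.latent_scores[
        [spk_index[s] for s in stimuli.table["speaker_id"]]
    ]  # stim x n_latent

    # deterministic per-stimulus signal (channels x time), unit-noise-SD scale
    sig = np.zeros((stimuli.n_stimuli, n_channels, len(times)))
    for l in range(n_latent):
        kern = _raised_cosine(times, *truth.effect_windows[l])
        sig += (
            latent_stim[:, l][:, None, None]
            * patterns[l][None, :, None]
            * kern[None, None, :]
            * truth.snr
        )
    if truth.acoustic_patterns is not None:
        drivers = truth.acoustic_drivers
        if drivers is None:
            raise ValueError("acoustic_patterns given without acoustic_drivers")
        a_snr = truth.snr if truth.acoustic_snr is None else truth.acoustic_snr
        for a in range(truth.acoustic_patterns.shape[0]):
            kern = _raised_cosine(times, *truth.acoustic_windows[a])
            sig += (
                drivers[:, a][:, None, None]
                * truth.acoustic_patterns[a][None, :, None]
                * kern[None, None, :]
                * a_snr
            )

    L = _spatial_chol(positions, neighbor_r)
    n_trials = design.n_trials
    # participant-specific noise stream (stable across processes)
    pid_key = zlib.crc32(participant_id.encode()) % (2**31)
    prng = np.random.default_rng([truth.seed, 53, pid_key])
    data = np.empty((n_trials, n_channels, len(times)))
    for i, tr in enumerate(design.trials):
        noise = L @ _pink_noise(prng, (n_channels, len(times)), sfreq)
        x = noise * noise_sd_uv
        if tr.trial_type == "experimental":
            x = x + sig[stim_index[tr.stimulus_id]] * noise_sd_uv
        data[i] = x
    if outlier_trial_rate > 0:
        bad = prng.random(n_trials) < outlier_trial_rate
        for i in np.where(bad)[0]:
            ch = int(prng.integers(n_channels))
            t0 = int(prng.integers(len(times) - 50))
            data[i, ch, t0 : t0 + 50] += 300.0

    meta = design.to_frame()[["stimulus_id", "trial_type", "block"]].copy()
    meta["keep_flag"] = True
    return EpochArray(
        data=data,
        times=times,
        channel_labels=labels,
        channel_positions=positions,
        trial_meta=meta,
        reference="common",
    )
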