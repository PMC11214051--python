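"""Ground-truth simulation scenarios exercising the full analysis chain.

Each scenario assembles a complete desk-scale experiment (16 stimuli =
8 speakers x 2 vowels, 8 participants, 20 repetitions, 10-ms grid) with a
known embedded representational structure, runs the neural-RDM and RSA
stages, and returns everything needed for group inference:

* :func:`recovery_scenario` — one characteristic's latent drives the scalp
  inside a known window; Model 1 should recover a cluster there.
* :func:`confound_scenario` — an early acoustic component correlated with a
  rated characteristic drives the scalp; Model 1 picks it up, Model 2
  (which partials the acoustic RDMs) should not, so M1 > M2 in the window.
* :func:`mixture_scenario` — one characteristic is constructed, rater by
  rater, as the rounded average of two others; Model 1 detects it but
  Model 3 (partialling the parent characteristics) should find nothing.
* :func:`latency_scenario` — a physical-like characteristic carries an
  early unique latent and a trait-like characteristic a late one; Model 3
  cluster onsets should preserve that ordering.

Signal-to-noise values are free parameters of the synthetic world, chosen
(and documented in the methods note) so that effects are comfortably inside
the detectable regime without being trivial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavioral as beh
from . import decoding as dec
from . import synthetic as syn
from .acoustic import AcousticRDMSet, acoustic_pca_rdms
from .containers import RDM, NeuralRDMSeries
from .rsa import RSATimeCourse, run_all_models

__all__ = [
    "ScenarioResult",
    "recovery_scenario",
    "confound_scenario",
    "mixture_scenario",
    "latency_scenario",
    "null_epochs",
]

DESK_N_PARTICIPANTS = 8
DESK_N_REPETITIONS = 20
DESK_SFREQ = 100.0


@dataclass
class ScenarioResult:
    courses: dict[tuple[str, str], RSATimeCourse]
    times: np.ndarray
    target: str
    true_window: tuple[float, float]
    neural: dict[str, NeuralRDMSeries] = field(default_factory=dict)
    behavioral_rdms: dict[str, RDM] = field(default_factory=dict)
    acoustic_rdms: AcousticRDMSet | None = None


def _run(
    stimuli,
    design,
    space,
    ratings,
    truth,
    seed: int,
    models: tuple[str, ...],
    n_participants: int = DESK_N_PARTICIPANTS,
    n_permutations: int = 5,
    acoustic_noise_sd: float = 0.5,
    acoustic_mixing: np.ndarray | None = None,
) -> tuple[dict, dict, AcousticRDMSet, np.ndarray, dict]:
    feat, ltas = syn.generate_acoustics(
        space, stimuli, seed=seed, noise_sd=acoustic_noise_sd, mixing=acoustic_mixing
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = beh.rater_agreement(ratings)
        means = beh.mean_ratings(ratings, screen)
        brdms = beh.behavioral_rdms(means)
        aset = acoustic_pca_rdms(feat, ltas)
        dcfg = dec.DecodingConfig(n_splits=5, n_permutations=n_permutations, seed=seed)
        neural = {}
        for p in range(n_participants):
            pid = f"p{p + 1:02d}"
            ep = syn.generate_eeg(
                design, space, truth, stimuli, sfreq=DESK_SFREQ, participant_id=pid
            )
            neural[pid] = dec.build_rdm_series(ep, dcfg, pid)
        courses = run_all_models(neural, brdms, aset, models=models)
    times = next(iter(neural.values())).times
    return courses, brdms, aset, times, neural


def _desk_stimuli_design(seed: int):
    stimuli = syn.make_stimulus_set(8, ("a", "i"))
    design = syn.generate_design(stimuli, n_repetitions=DESK_N_REPETITIONS, seed=seed)
    return stimuli, design


def recovery_scenario(
    seed: int,
    snr: float = 1.5,
    window: tuple[float, float] = (100.0, 300.0),
    target: str = "trustworthiness",
    models: tuple[str, ...] = ("M1",),
) -> ScenarioResult:
    """Latent-driven signal in a known window; target loads on latent 1."""
    stimuli, design = _desk_stimuli_design(seed)
    space = syn.generate_latent_space(8, 2, syn.default_loading_spec(2), seed=seed)
    truth = syn.SyntheticTruth(effect_windows=(window, window), snr=snr, seed=seed)
    ratings = syn.generate_ratings(space, stimuli, n_raters=20, seed=seed)
    courses, brdms, aset, times, neural = _run(
        stimuli, design, space, ratings, truth, seed, models
    )
    return ScenarioResult(
        courses=courses, times=times, target=target, true_window=window,
        neural=neural, behavioral_rdms=brdms, acoustic_rdms=aset,
    )


def confound_scenario(
    seed: int,
    acoustic_snr: float = 2.5,
    window: tuple[float, float] = (60.0, 160.0),
    target: str = "gender",
) -> ScenarioResult:
    """Early acoustic confound: the physical latent reaches the scalp only
    through an acoustic pathway that the acoustic feature table also tracks
    (F0/formants), so Model 2's covariates can explain it away."""
    stimuli, design = _desk_stimuli_design(seed)
    space = syn.generate_latent_space(8, 2, syn.default_loading_spec(2), seed=seed)
    spk = {s: i for i, s in enumerate(stimuli.speaker_ids)}
    drivers = space.latent_scores[
        [spk[s] for s in stimuli.table["speaker_id"]], 1
    ][:, None]
    rng = np.random.default_rng([seed, 97])
    apat = rng.standard_normal((1, 32))
    apat /= np.linalg.norm(apat)
    truth = syn.SyntheticTruth(
        effect_windows=((400.0, 500.0), (400.0, 500.0)),
        snr=0.0,
        seed=seed,
        acoustic_patterns=apat,
        acoustic_windows=(window,),
        acoustic_drivers=drivers,
        acoustic_snr=acoustic_snr,
    )
    ratings = syn.generate_ratings(space, stimuli, n_raters=20, seed=seed)
    courses, brdms, aset, times, neural = _run(
        stimuli, design, space, ratings, truth, seed, ("M1", "M2"),
        acoustic_noise_sd=0.3,
    )
    return ScenarioResult(
        courses=courses, times=times, target=target, true_window=window,
        neural=neural, behavioral_rdms=brdms, acoustic_rdms=aset,
    )


def _mixture_ratings(space, stimuli, seed: int) -> pd.DataFrame:
    """Ratings in which health is, rater by rater, the rounded average of
    trustworthiness and dominance."""
    ratings = syn.generate_ratings(
        space, stimuli, n_raters=20, rater_noise_sd=0.5, seed=seed,
        stimulus_jitter_sd=0.1,
    )
    wide = ratings.pivot_table(
        index=["rater_id", "stimulus_id"], columns="characteristic", values="rating"
    )
    mix = np.clip(
        np.rint((wide["trustworthiness"] + wide["dominance"]) / 2.0), 1, 9
    ).astype(int)
    ratings = ratings[ratings["characteristic"] != "health"]
    extra = mix.rename("rating").reset_index()
    extra["characteristic"] = "health"
    return pd.concat([ratings, extra], ignore_index=True)


def mixture_scenario(seed: int, snr: float = 0.8) -> ScenarioResult:
    """Emergent characteristic: health is a pure mixture of trustworthiness
    and dominance, which are themselves noise-free expressions of latent 1 —
    the only latent allowed to reach the scalp."""
    idx = {c: i for i, c in enumerate(syn.CHARACTERISTICS)}
    spec = syn.default_loading_spec(2).copy()
    uniq = np.sqrt(np.clip(1 - (spec**2).sum(axis=0), 0, None))
    for c in ("trustworthiness", "dominance"):
        spec[0, idx[c]] = 1.0
        spec[1, idx[c]] = 0.0
        uniq[idx[c]] = 0.0
    stimuli, design = _desk_stimuli_design(seed)
    space = syn.generate_latent_space(8, 2, spec, seed=seed, uniqueness=uniq)
    ratings = _mixture_ratings(space, stimuli, seed)
    rng = np.random.default_rng([seed, 77])
    pat = rng.standard_normal((2, 32))
    pat /= np.linalg.norm(pat, axis=1, keepdims=True)
    pat[1] = 0.0  # latent 2 shapes ratings and acoustics but not the EEG
    truth = syn.SyntheticTruth(
        effect_windows=((100.0, 250.0), (200.0, 350.0)), snr=snr, seed=seed,
        scalp_patterns=pat,
    )
    courses, brdms, aset, times, neural = _run(
        stimuli, design, space, ratings, truth, seed, ("M1", "M3")
    )
    return ScenarioResult(
        courses=courses, times=times, target="health", true_window=(100.0, 250.0),
        neural=neural, behavioral_rdms=brdms, acoustic_rdms=aset,
    )


def latency_scenario(
    seed: int,
    snr: float = 1.5,
    early_window: tuple[float, float] = (80.0, 200.0),
    late_window: tuple[float, float] = (350.0, 500.0),
) -> ScenarioResult:
    """Physical-like characteristic (gender) with an early unique latent and
    a trait-like characteristic (trustworthiness) with a late one; Model 3
    clusters should appear earlier for the physical characteristic.

    Acoustics are generated independent of the trait space here (zero
    mixing) so the acoustic covariates do not absorb the unique latents, and
    ratings are comparatively clean so partialling leaves little cross-talk
    between the two latents.
    """
    idx = {c: i for i, c in enumerate(syn.CHARACTERISTICS)}
    spec = np.zeros((2, len(syn.CHARACTERISTICS)))
    spec[0, idx["trustworthiness"]] = 0.95  # late trait latent
    spec[0, idx["dominance"]] = 0.4
    spec[0, idx["educatedness"]] = 0.4
    spec[0, idx["professionalism"]] = 0.4
    spec[1, idx["gender"]] = 0.95  # early physical latent
    spec[1, idx["attractiveness"]] = 0.4
    spec[1, idx["age"]] = 0.4
    spec[0, idx["health"]] = 0.4
    stimuli, design = _desk_stimuli_design(seed)
    space = syn.generate_latent_space(8, 2, spec, seed=seed)
    truth = syn.SyntheticTruth(
        effect_windows=(late_window, early_window), snr=snr, seed=seed
    )
    ratings = syn.generate_ratings(
        space, stimuli, n_raters=20, rater_noise_sd=0.5, seed=seed,
        stimulus_jitter_sd=0.1,
    )
    courses, brdms, aset, times, neural = _run(
        stimuli, design, space, ratings, truth, seed, ("M3",),
        acoustic_mixing=np.zeros((13, 2)),
    )
    return ScenarioResult(
        courses=courses, times=times, target="gender", true_window=early_window,
        neural=neural, behavioral_rdms=brdms, acoustic_rdms=aset,
    )


def null_epochs(seed: int, n_trials_per_stimulus: int = 20):
    """Label-uninformative epochs (snr = 0): 16 stimuli x 20 trials on the
    desk grid; used for chance calibration of the decoding stage."""
    stimuli = syn.make_stimulus_set(8, ("a", "i"))
    design = syn.generate_design(stimuli, n_repetitions=n_trials_per_stimulus, seed=seed)
    space = syn.generate_latent_space(8, 2, syn.default_loading_spec(2), seed=seed)
    truth = syn.SyntheticTruth(
        effect_windows=((100.0, 300.0), (150.0, 350.0)), snr=0.0, seed=seed
    )
    return syn.generate_eeg(design, space, truth, stimuli, sfreq=DESK_SFREQ)
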