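"""End-to-end orchestration: simulate -> preprocess -> decode -> behavior ->
acoustics -> RSA -> inference, with per-stage outputs and a manifest that
makes re-runs bit-identical under a fixed seed."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import behavioral as beh
from . import decoding, inference, preprocessing, rsa, synthetic
from .acoustic import acoustic_pca_rdms
from .config import PipelineConfig
from .io import (
    save_rdm_series,
    write_ltas_csv,
    write_ratings_csv,
    write_timecourses_csv,
)

__all__ = ["run_pipeline", "simulate_dataset"]

log = logging.getLogger("voicersa")


def _pca_report(sol) -> dict:
    return {
        "n_components": sol.n_components,
        "variance_explained_pct": sol.variance_explained_pct,
        "eigenvalues": list(sol.eigenvalues),
        "pattern_loadings": [list(row) for row in sol.pattern_loadings],
        "factor_correlations": [list(row) for row in sol.factor_correlations],
        "variables": sol.variable_names,
    }


def simulate_dataset(cfg: PipelineConfig):
    """Generate one synthetic experiment (stimuli, design, space, ratings,
    acoustics, per-participant EEG) from a pipeline config."""
    stimuli = synthetic.make_stimulus_set(cfg.n_speakers, cfg.vowels)
    design = synthetic.generate_design(
        stimuli,
        n_repetitions=cfg.n_repetitions,
        vigilance_stimuli=cfg.vigilance_stimuli,
        vigilance_repetitions=cfg.vigilance_repetitions,
        n_blocks=cfg.n_blocks,
        seed=cfg.seed,
    )
    n_latent = len(cfg.effect_windows)
    space = synthetic.generate_latent_space(
        cfg.n_speakers, n_latent, synthetic.default_loading_spec(n_latent), seed=cfg.seed
    )
    ratings = synthetic.generate_ratings(
        space, stimuli, n_raters=cfg.n_raters, rater_noise_sd=cfg.rater_noise_sd,
        seed=cfg.seed,
    )
    features, ltas = synthetic.generate_acoustics(space, stimuli, seed=cfg.seed)
    truth = synthetic.SyntheticTruth(
        effect_windows=cfg.effect_windows, snr=cfg.snr, seed=cfg.seed
    )
    epochs = {}
    for p in range(cfg.n_participants):
        pid = f"p{p + 1:02d}"
        epochs[pid] = synthetic.generate_eeg(
            design,
            space,
            truth,
            stimuli,
            n_channels=cfg.n_channels,
            sfreq=cfg.sfreq,
            noise_sd_uv=cfg.noise_sd_uv,
            outlier_trial_rate=cfg.outlier_trial_rate,
            participant_id=pid,
        )
    return stimuli, design, space, ratings, features, ltas, truth, epochs


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage, write per-stage outputs and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulate: %d stimuli x %d reps, %d participants",
             cfg.n_speakers * len(cfg.vowels), cfg.n_repetitions, cfg.n_participants)
    stimuli, design, space, ratings, features, ltas, truth, epochs = simulate_dataset(cfg)
    write_ratings_csv(out / "ratings.csv", ratings)
    features.to_csv(out / "acoustic_features.csv", index=False)
    write_ltas_csv(out / "ltas.csv", ltas)
    cfg.save(out / "config.yaml")

    qc_reports = {}
    clean = {}
    for pid, ep in epochs.items():
        clean[pid], qc_reports[pid] = preprocessing.preprocess(
            ep,
            bad_channel_threshold_sd=cfg.bad_channel_threshold_sd,
            peak_to_peak_uv=cfg.peak_to_peak_uv,
            low_hz=cfg.low_hz,
            high_hz=cfg.high_hz,
            filter_order=cfg.filter_order,
            baseline_ms=cfg.baseline_ms,
            reference_labels=cfg.reference_labels,
        )
        log.info("preprocess %s: %d bad channels, %.2f%% trials rejected", pid,
                 qc_reports[pid]["n_channels_interpolated"],
                 qc_reports[pid]["pct_trials_rejected"])
    (out / "qc.json").write_text(json.dumps(qc_reports, indent=2))

    dconf = decoding.DecodingConfig(
        n_splits=cfg.n_splits,
        n_permutations=cfg.n_permutations,
        svm_cost=cfg.svm_cost,
        seed=cfg.seed,
        shrinkage_mode=cfg.shrinkage_mode,
    )
    neural = {}
    for pid, ep in clean.items():
        neural[pid] = decoding.build_rdm_series(ep, dconf, participant_id=pid)
        save_rdm_series(out / f"rdm_{pid}.h5", neural[pid], config_echo=dconf.__dict__)

    screen = beh.rater_agreement(
        ratings, max_same_fraction=cfg.max_same_fraction, icc_threshold=cfg.icc_threshold
    )
    means = beh.mean_ratings(ratings, screen)
    means.values.to_csv(out / "mean_ratings.csv")
    beh.characteristic_correlations(means).to_csv(out / "characteristic_correlations.csv")
    rating_pca = beh.pca_oblimin(
        means.values.to_numpy(), variable_names=means.characteristics,
        item_names=means.stimulus_ids,
    )
    (out / "rating_pca.json").write_text(json.dumps(_pca_report(rating_pca), indent=2))
    behavioral_rdms = beh.behavioral_rdms(means)
    acoustic_set = acoustic_pca_rdms(features, ltas)
    (out / "acoustic_pca.json").write_text(
        json.dumps(_pca_report(acoustic_set.pca), indent=2)
    )

    courses = rsa.run_all_models(neural, behavioral_rdms, acoustic_set, models=cfg.models)
    write_timecourses_csv(out / "timecourses.csv", courses)

    iconf = inference.InferenceConfig(
        z_threshold_one_sided=cfg.z_threshold_one_sided,
        z_threshold_two_sided=cfg.z_threshold_two_sided,
        n_iterations=cfg.n_iterations,
        alpha=cfg.alpha,
        seed=cfg.seed,
    )
    results = {}
    times = next(iter(neural.values())).times
    for (char, model), tc in courses.items():
        res = inference.cluster_onesample(tc.rho, times, iconf)
        results[f"{char}:{model}"] = {
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "cluster_z": c.cluster_z,
                    "corrected_p": c.corrected_p,
                }
                for c in res.significant()
            ],
            "peak_time_ms": res.peak_time_ms,
            "peak_rho": res.peak_statistic,
        }
    # mean decoding time course across participants
    mean_dec = np.vstack(
        [decoding.mean_decoding_timecourse(s) for s in neural.values()]
    )
    dec_res = inference.cluster_onesample(mean_dec - 0.5, times, iconf)
    dec_peak = inference.peak_statistics(
        mean_dec, times, null_value=0.5, clusters=dec_res.significant()
    )
    results["voice_decoding"] = {
        "clusters": [
            {"start_ms": c.start_ms, "end_ms": c.end_ms, "corrected_p": c.corrected_p}
            for c in dec_res.significant()
        ],
        "peak_time_ms": dec_peak.time_ms,
        "peak_accuracy": dec_peak.mean,
        "t": dec_peak.t_value,
        "cohens_d": dec_peak.cohens_d,
    }
    (out / "inference.json").write_text(json.dumps(results, indent=2))

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "preset": cfg.preset,
        "stages": ["simulate", "preprocess", "rdm", "behavior", "acoustics", "rsa", "infer"],
        "n_participants": cfg.n_participants,
        "n_stimuli": stimuli.n_stimuli,
        "dropped_characteristics": screen.dropped_characteristics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
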