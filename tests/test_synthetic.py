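"""Design arithmetic, latent-space structure and generator determinism."""

import numpy as np
import pandas as pd
import pytest

from voicersa import synthetic as syn


class TestStimulusSet:
    def test_full_set_counts(self):
        s = syn.make_stimulus_set(32)
        assert s.n_stimuli == 96
        assert s.n_speakers == 32
        per_speaker = s.table.groupby("speaker_id").size()
        assert (per_speaker == 3).all()
        genders = s.table.drop_duplicates("speaker_id")["speaker_gender"].value_counts()
        assert genders.tolist() == [16, 16]
        ages = s.table.drop_duplicates("speaker_id")["speaker_age_group"].value_counts()
        assert ages.tolist() == [16, 16]

    def test_unbalanced_speaker_count_rejected(self):
        with pytest.raises(ValueError, match="multiple of 4"):
            syn.make_stimulus_set(6)


class TestDesign:
    def test_paper_scale_trial_arithmetic(self):
        stim = syn.make_stimulus_set(32)
        d = syn.generate_design(
            stim, n_repetitions=40, vigilance_stimuli=24, vigilance_repetitions=16,
            n_blocks=6, seed=0,
        )
        assert d.n_experimental() == 3840
        assert d.n_vigilance() == 384
        assert d.n_trials == 4224
        per_block = d.to_frame().groupby("block").size()
        assert (per_block == 704).all()
        assert d.vigilance_presentations() == 576

    def test_degenerate_single_trial(self):
        stim = syn.make_stimulus_set(4, ("a",))
        d = syn.generate_design(stim, n_repetitions=1, n_blocks=1, seed=0)
        # 4 stimuli x 1 rep; with one stimulus per speaker the minimal set is 4
        assert d.n_trials == 4

    def test_vigilance_placement_constraints(self):
        stim = syn.make_stimulus_set(8, ("a", "i"))
        d = syn.generate_design(
            stim, n_repetitions=10, vigilance_stimuli=4, vigilance_repetitions=5,
            n_blocks=2, seed=3,
        )
        df = d.to_frame()
        for _, block in df.groupby("block"):
            kinds = block["trial_type"].to_numpy()
            assert kinds[0] == "experimental"  # never first in a block
            vig = kinds != "experimental"
            assert not np.any(vig[:-1] & vig[1:])  # never consecutive

    def test_jitter_within_range(self):
        stim = syn.make_stimulus_set(4, ("a",))
        d = syn.generate_design(stim, n_repetitions=5, seed=1)
        soa = d.to_frame()["onset_asynchrony_ms"]
        assert soa.between(800, 1000).all()

    def test_indivisible_block_split_rejected(self):
        stim = syn.make_stimulus_set(8, ("a", "i"))
        with pytest.raises(ValueError, match="evenly"):
            syn.generate_design(stim, n_repetitions=10, n_blocks=7, seed=0)

    def test_insufficient_vigilance_spacing_rejected(self):
        stim = syn.make_stimulus_set(4, ("a",))
        with pytest.raises(ValueError, match="insufficient slots"):
            syn.generate_design(
                stim, n_repetitions=1, vigilance_stimuli=5, vigilance_repetitions=1,
                n_blocks=1, seed=0,
            )

    def test_deterministic_under_seed(self):
        stim = syn.make_stimulus_set(8, ("a", "i"))
        d1 = syn.generate_design(stim, n_repetitions=5, seed=9)
        d2 = syn.generate_design(stim, n_repetitions=5, seed=9)
        pd.testing.assert_frame_equal(d1.to_frame(), d2.to_frame())


class TestLatentSpace:
    def test_identity_loadings_recover_latent_correlations(self):
        spec = np.zeros((8, 8))
        np.fill_diagonal(spec, 1.0)
        space = syn.generate_latent_space(20, 8, spec, seed=0)
        corr = space.implied_correlations()
        assert np.allclose(corr, np.eye(8))

    def test_single_latent_full_loading_gives_unit_correlations(self):
        spec = np.ones((1, 8))
        space = syn.generate_latent_space(10, 1, spec, seed=0, uniqueness=np.zeros(8))
        assert np.allclose(space.implied_correlations(), 1.0)

    def test_scores_exactly_standardized(self):
        space = syn.generate_latent_space(16, 2, syn.default_loading_spec(2), seed=4)
        assert np.allclose(space.latent_scores.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(space.latent_scores.std(axis=0), 1, atol=1e-12)

    def test_monte_carlo_rating_correlations_match_closed_form(self):
        """Empirical mean-rating correlations approach the implied values."""
        spec = np.array(
            [[0.9, 0.9, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0],
             [0.0, 0.0, 0.9, 0.9, 0.5, 0.0, 0.0, 0.0]]
        )
        space = syn.generate_latent_space(32, 2, spec, seed=2)
        stim = syn.make_stimulus_set(32)
        ratings = syn.generate_ratings(
            space, stim, n_raters=20, rater_noise_sd=0.3, seed=2,
            stimulus_jitter_sd=0.05, include_low_agreement_scale=False,
        )
        means = ratings.pivot_table(
            index="stimulus_id", columns="characteristic", values="rating"
        )[list(syn.CHARACTERISTICS)]
        emp = np.corrcoef(means.to_numpy(), rowvar=False)
        implied = space.implied_correlations()
        strong = np.abs(implied) > 0.3
        assert np.max(np.abs(emp[strong] - implied[strong])) < 0.1

    def test_excess_communality_rejected(self):
        spec = np.full((2, 8), 0.9)
        with pytest.raises(ValueError, match="communalities"):
            syn.generate_latent_space(10, 2, spec, seed=0)


class TestRatings:
    def test_zero_noise_raters_identical_and_clipped(self, stimuli16):
        spec = np.ones((1, 8))
        space = syn.generate_latent_space(8, 1, spec, seed=1, uniqueness=np.zeros(8))
        # extreme scaling pushes ratings onto the 1..9 boundary
        r = syn.generate_ratings(
            space, stimuli16, n_raters=3, rater_noise_sd=0.0, seed=1,
            stimulus_jitter_sd=0.0, scale_sd=30.0, include_low_agreement_scale=False,
        )
        wide = r.pivot_table(
            index="stimulus_id", columns="rater_id", values="rating", aggfunc="mean"
        )
        assert (wide.nunique(axis=1) == 1).all()  # all raters agree exactly
        # extreme latents are clipped at both scale boundaries
        assert r["rating"].min() == 1 and r["rating"].max() == 9

    def test_ratings_in_range_and_integer(self, ratings16):
        assert ratings16["rating"].between(1, 9).all()
        assert (ratings16["rating"] % 1 == 0).all()

    def test_low_agreement_scale_present(self, ratings16):
        assert syn.LOW_AGREEMENT_CHARACTERISTIC in set(ratings16["characteristic"])


class TestAcousticsGeneration:
    def test_zero_mixing_decouples_acoustics_from_traits(self, space2, stimuli16):
        from voicersa.rsa import spearman_partial, vectorize_rdm

        rhos = []
        for seed in range(30):
            feat, ltas = syn.generate_acoustics(
                space2, stimuli16, seed=seed, mixing=np.zeros((13, 2))
            )
            f0 = feat["F0_mean"].to_numpy()
            acou = np.abs(f0[:, None] - f0[None, :])
            spk = stimuli16.table["speaker_id"].map(
                {s: i for i, s in enumerate(stimuli16.speaker_ids)}
            ).to_numpy()
            lat = space2.latent_scores[spk, 1]
            behav = np.abs(lat[:, None] - lat[None, :])
            rhos.append(spearman_partial(vectorize_rdm(acou), vectorize_rdm(behav)))
        assert abs(np.mean(rhos)) < 0.05

    def test_identity_mixing_recovers_latent_in_pc1(self, stimuli16):
        from voicersa.factors import pca_oblimin
        from voicersa.synthetic import ACOUSTIC_MEASURES

        space = syn.generate_latent_space(8, 1, syn.default_loading_spec(1), seed=3)
        mixing = np.ones((13, 1)) * 2.0  # every measure strongly tracks latent 1
        feat, _ = syn.generate_acoustics(
            space, stimuli16, seed=3, mixing=mixing, noise_sd=0.2
        )
        sol = pca_oblimin(feat[list(ACOUSTIC_MEASURES)].to_numpy())
        spk = stimuli16.table["speaker_id"].map(
            {s: i for i, s in enumerate(stimuli16.speaker_ids)}
        ).to_numpy()
        lat = space.latent_scores[spk, 0]
        r = np.corrcoef(sol.component_scores[:, 0], lat)[0, 1]
        assert abs(r) > 0.9

    def test_ltas_nonnegative_and_vowel_dependent(self, space2, stimuli16):
        _, ltas = syn.generate_acoustics(space2, stimuli16, seed=7)
        assert np.all(ltas.spectra >= 0)
        # same speaker, different vowels must differ spectrally
        assert not np.allclose(ltas.spectra[0], ltas.spectra[1])


class TestEEGGeneration:
    def test_same_stimulus_shares_deterministic_part(self, design16, space2, stimuli16):
        truth = syn.SyntheticTruth(effect_windows=((100, 300), (150, 350)), snr=1.0, seed=5)
        a = syn.generate_eeg(design16, space2, truth, stimuli16, n_channels=16, sfreq=100.0)
        b = syn.generate_eeg(design16, space2, truth, stimuli16, n_channels=16, sfreq=100.0)
        np.testing.assert_array_equal(a.data, b.data)  # bit-identical re-run

    def test_window_outside_epoch_rejected(self, design16, space2, stimuli16):
        truth = syn.SyntheticTruth(effect_windows=((100, 800), (150, 350)), snr=1.0, seed=5)
        with pytest.raises(ValueError, match="outside epoch"):
            syn.generate_eeg(design16, space2, truth, stimuli16, sfreq=100.0)

    def test_snr_zero_has_no_stimulus_information(self, design16, space2, stimuli16):
        truth = syn.SyntheticTruth(effect_windows=((100, 300), (150, 350)), snr=0.0, seed=5)
        ep = syn.generate_eeg(design16, space2, truth, stimuli16, n_channels=16, sfreq=100.0)
        df = ep.trial_meta
        means = {}
        for sid, grp in df.groupby("stimulus_id"):
            means[sid] = ep.data[grp.index].mean(axis=0)
        # per-stimulus means differ only through noise: grand spread is tiny
        stack = np.stack(list(means.values()))
        assert stack.std(axis=0).mean() < 2.0  # noise-only scale (5 uV / sqrt(10))
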