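"""Subaveraging, noise normalization and pairwise decoding."""

import numpy as np
import pandas as pd
import pytest

from voicersa import decoding as dec
from conftest import make_epochs


def _epochs_two_classes(rng, sep=0.0, n_per=10, n_ch=8, n_t=5):
    """Two stimuli, optionally separated along a random channel pattern."""
    data = rng.standard_normal((2 * n_per, n_ch, n_t))
    pattern = rng.standard_normal(n_ch)
    pattern /= np.linalg.norm(pattern)
    data[n_per:] += sep * pattern[None, :, None]
    meta = pd.DataFrame(
        {
            "stimulus_id": ["a"] * n_per + ["b"] * n_per,
            "trial_type": "experimental",
            "keep_flag": True,
        }
    )
    return make_epochs(data, meta=meta)


class TestSubaverage:
    def test_balanced_splits_and_exact_means(self):
        rng = np.random.default_rng(0)
        ep = _epochs_two_classes(rng, n_per=10)
        cfg = dec.DecodingConfig(n_splits=5, seed=1)
        ps = dec.subaverage(ep, cfg, 0)
        assert ps.averages.shape[:2] == (2, 5)
        assert (ps.counts == 2).all()  # 10 trials over 5 splits
        # pooled mean of pseudo-trials equals the brute-force trial mean
        np.testing.assert_allclose(
            ps.averages[0].mean(axis=0), ep.data[:10].mean(axis=0), atol=1e-12
        )

    def test_identical_trials_give_identical_pseudotrials(self):
        data = np.tile(np.arange(40.0).reshape(1, 8, 5), (12, 1, 1))
        meta = pd.DataFrame(
            {"stimulus_id": ["a"] * 6 + ["b"] * 6, "trial_type": "experimental",
             "keep_flag": True}
        )
        ep = make_epochs(data, meta=meta)
        ps = dec.subaverage(ep, dec.DecodingConfig(n_splits=3, seed=0), 0)
        for s in range(2):
            for k in range(3):
                np.testing.assert_array_equal(ps.averages[s, k], data[0])

    def test_same_seed_and_permutation_reproduce_assignment(self):
        rng = np.random.default_rng(1)
        ep = _epochs_two_classes(rng, n_per=11)  # odd remainder
        cfg = dec.DecodingConfig(n_splits=5, seed=3)
        a = dec.subaverage(ep, cfg, 4)
        b = dec.subaverage(ep, cfg, 4)
        np.testing.assert_array_equal(a.averages, b.averages)
        c = dec.subaverage(ep, cfg, 5)
        assert not np.allclose(a.averages, c.averages)

    def test_too_few_trials_names_stimulus(self):
        rng = np.random.default_rng(2)
        ep = _epochs_two_classes(rng, n_per=3)
        with pytest.raises(ValueError, match="'a'"):
            dec.subaverage(ep, dec.DecodingConfig(n_splits=5, seed=0), 0)


class TestNoiseNormalizer:
    def _pseudo_from_residuals(self, resid):
        # wrap residuals (stim x split x ch x time) as a PseudoTrialSet
        S, k, C, T = resid.shape
        return dec.PseudoTrialSet(
            averages=resid,
            counts=np.ones((S, k), dtype=int),
            stimulus_ids=[f"s{i}" for i in range(S)],
            times=np.arange(T, dtype=float),
        )

    def test_identity_covariance_gives_identity_whitening(self):
        rng = np.random.default_rng(3)
        resid = rng.standard_normal((4, 6, 5, 200))
        ps = self._pseudo_from_residuals(resid)
        norm = dec.fit_noise_normalizer(ps, shrinkage_mode="fixed", shrinkage=0.0)
        # large-sample empirical covariance of white residuals ~ identity
        assert np.abs(norm.whitening_matrix - np.eye(5)).max() < 0.15

    def test_diagonal_covariance_scales_channels(self):
        rng = np.random.default_rng(4)
        resid = rng.standard_normal((8, 6, 2, 500))
        resid[:, :, 0, :] *= 2.0  # channel variance 4 vs 1
        ps = self._pseudo_from_residuals(resid)
        norm = dec.fit_noise_normalizer(ps, shrinkage_mode="fixed", shrinkage=0.0)
        ratio = norm.whitening_matrix[0, 0] / norm.whitening_matrix[1, 1]
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_whitening_inverts_covariance_exactly(self):
        rng = np.random.default_rng(5)
        resid = rng.standard_normal((6, 5, 6, 100))
        ps = self._pseudo_from_residuals(resid)
        norm = dec.fit_noise_normalizer(ps, shrinkage_mode="fixed", shrinkage=0.0)
        W, S = norm.whitening_matrix, norm.covariance
        assert np.abs(W @ S @ W - np.eye(6)).max() < 1e-8

    def test_singular_covariance_suggests_shrinkage(self):
        resid = np.zeros((2, 3, 4, 10))
        resid[:, :, 0, :] = np.random.default_rng(6).standard_normal((2, 3, 10))
        ps = self._pseudo_from_residuals(resid)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            dec.fit_noise_normalizer(ps, shrinkage_mode="fixed", shrinkage=0.0)


class TestPairwiseDecode:
    def test_identical_stimuli_decode_at_chance_on_average(self):
        rng = np.random.default_rng(7)
        accs = []
        for seed in range(20):
            ep = _epochs_two_classes(np.random.default_rng(seed), sep=0.0)
            cfg = dec.DecodingConfig(n_splits=5, seed=seed)
            ps = dec.subaverage(ep, cfg, 0)
            accs.append(dec.pairwise_decode(ps, "a", "b", 2, cfg))
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_widely_separated_classes_decode_perfectly(self):
        ep = _epochs_two_classes(np.random.default_rng(8), sep=30.0)
        cfg = dec.DecodingConfig(n_splits=5, seed=0)
        ps = dec.subaverage(ep, cfg, 0)
        assert dec.pairwise_decode(ps, "a", "b", 2, cfg) == 1.0

    def test_pair_order_symmetry(self):
        ep = _epochs_two_classes(np.random.default_rng(9), sep=1.0)
        cfg = dec.DecodingConfig(n_splits=5, seed=0)
        ps = dec.subaverage(ep, cfg, 0)
        assert dec.pairwise_decode(ps, "a", "b", 1, cfg) == pytest.approx(
            dec.pairwise_decode(ps, "b", "a", 1, cfg)
        )


class TestRDMSeries:
    def test_symmetry_and_nan_diagonal(self, epochs16):
        cfg = dec.DecodingConfig(n_splits=5, n_permutations=1, seed=0)
        series = dec.build_rdm_series(epochs16, cfg, "p")
        v = series.values
        assert np.isnan(v[:, np.arange(16), np.arange(16)]).all()
        off = ~np.eye(16, dtype=bool)
        np.testing.assert_array_equal(v[:, off], np.swapaxes(v, 1, 2)[:, off])

    def test_determinism(self, epochs16):
        cfg = dec.DecodingConfig(n_splits=5, n_permutations=2, seed=5)
        a = dec.build_rdm_series(epochs16, cfg, "p")
        b = dec.build_rdm_series(epochs16, cfg, "p")
        np.testing.assert_array_equal(a.values, b.values)

    def test_permutation_averaging_shrinks_variance(self):
        """Entry variance across split assignments drops roughly with the
        number of subaveraging permutations."""
        rng = np.random.default_rng(11)
        ep = _epochs_two_classes(rng, sep=0.8, n_per=10, n_ch=8, n_t=3)
        v1, v8 = [], []
        for seed in range(12):
            c1 = dec.DecodingConfig(n_splits=5, n_permutations=1, seed=seed)
            c8 = dec.DecodingConfig(n_splits=5, n_permutations=8, seed=seed)
            v1.append(dec.build_rdm_series(ep, c1).values[1, 0, 1])
            v8.append(dec.build_rdm_series(ep, c8).values[1, 0, 1])
        assert np.var(v8) < np.var(v1)

    def test_embedded_two_cluster_geometry_recovered(self):
        """Stimuli split into two pattern groups: between-group accuracy
        exceeds within-group accuracy at the signal sample."""
        rng = np.random.default_rng(12)
        n_per, n_ch, n_t = 8, 8, 3
        ids = [f"s{i}" for i in range(4)]
        pattern = rng.standard_normal(n_ch)
        pattern /= np.linalg.norm(pattern)
        rows, data = [], []
        for si, sid in enumerate(ids):
            group = si // 2
            x = rng.standard_normal((n_per, n_ch, n_t))
            x[:, :, 1] += (3.0 if group else -3.0) * pattern[None, :]
            data.append(x)
            rows += [sid] * n_per
        meta = pd.DataFrame(
            {"stimulus_id": rows, "trial_type": "experimental", "keep_flag": True}
        )
        ep = make_epochs(np.concatenate(data), meta=meta)
        cfg = dec.DecodingConfig(n_splits=4, n_permutations=3, seed=0)
        series = dec.build_rdm_series(ep, cfg)
        v = series.values[1]
        between = np.mean([v[0, 2], v[0, 3], v[1, 2], v[1, 3]])
        within = np.mean([v[0, 1], v[2, 3]])
        assert between > within

    def test_mean_timecourse_arithmetic(self):
        times = np.arange(3.0)
        vals = np.full((3, 4, 4), 0.5)
        np.fill_diagonal(vals[0], np.nan)
        np.fill_diagonal(vals[1], np.nan)
        np.fill_diagonal(vals[2], np.nan)
        vals[1, 0, 1] = vals[1, 1, 0] = 1.0  # one pair of six at 1.0
        from voicersa.containers import NeuralRDMSeries

        series = NeuralRDMSeries(values=vals, times=times, items=list("abcd"))
        mt = dec.mean_decoding_timecourse(series)
        assert mt[0] == pytest.approx(0.5)
        assert mt[1] == pytest.approx((5 * 0.5 + 1.0) / 6)
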