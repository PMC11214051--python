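"""Cluster-based permutation inference and peak statistics."""

import numpy as np
import pytest
from scipy import stats

from voicersa import inference as inf


def _cfg(**kw):
    kw.setdefault("n_iterations", 200)
    kw.setdefault("seed", 0)
    return inf.InferenceConfig(**kw)


class TestThresholds:
    def test_printed_thresholds(self):
        assert round(inf.normal_quantile_threshold(0.05, "one"), 2) == 1.64
        assert round(inf.normal_quantile_threshold(0.05, "two"), 2) == 1.96

    def test_median_alpha_gives_zero(self):
        assert inf.normal_quantile_threshold(0.5, "one") == pytest.approx(0.0)

    def test_out_of_range_alpha_rejected(self):
        with pytest.raises(ValueError):
            inf.normal_quantile_threshold(0.0, "one")


class TestOneSample:
    def test_zero_data_produces_no_clusters(self):
        res = inf.cluster_onesample(np.zeros((6, 20)), np.arange(20.0), _cfg())
        assert res.clusters == []

    def test_strong_offset_recovered_in_window(self):
        rng = np.random.default_rng(0)
        hits = 0
        times = np.arange(60.0)
        for seed in range(10):
            data = rng.standard_normal((12, 60))
            data[:, 20:40] += 1.5
            res = inf.cluster_onesample(data, times, _cfg(n_iterations=500, seed=seed))
            sig = res.significant()
            covered = np.zeros(60, bool)
            for c in sig:
                covered[c.start_index : c.end_index + 1] = True
            if covered[20:40].mean() >= 0.8:
                hits += 1
        assert hits >= 9

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((10, 50))
        data[:, 10:20] += 2.0
        res_a = inf.cluster_onesample(data, np.arange(50.0), _cfg())
        shifted = np.roll(data, 15, axis=1)
        res_b = inf.cluster_onesample(shifted, np.arange(50.0), _cfg())
        starts_a = sorted(c.start_index for c in res_a.significant())
        starts_b = sorted(c.start_index for c in res_b.significant())
        assert [s + 15 for s in starts_a] == starts_b

    def test_participant_order_invariance(self):
        """Cluster geometry is exactly order-invariant; corrected p values
        agree within Monte-Carlo error of the sign-flip null."""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((8, 40))
        data[:, 5:15] += 1.0
        res_a = inf.cluster_onesample(data, np.arange(40.0), _cfg(n_iterations=2000))
        res_b = inf.cluster_onesample(data[::-1], np.arange(40.0), _cfg(n_iterations=2000))
        assert [(c.start_index, c.end_index) for c in res_a.clusters] == [
            (c.start_index, c.end_index) for c in res_b.clusters
        ]
        for ca, cb in zip(res_a.clusters, res_b.clusters):
            assert ca.corrected_p == pytest.approx(cb.corrected_p, abs=0.05)

    def test_corrected_p_monotone_in_cluster_size(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((10, 80)) * 0.5
        data[:, 10:30] += 1.2  # long cluster
        data[:, 60:64] += 1.2  # short cluster
        res = inf.cluster_onesample(data, np.arange(80.0), _cfg(n_iterations=500))
        by_size = sorted(res.clusters, key=lambda c: c.size)
        ps = [c.corrected_p for c in by_size]
        assert all(ps[i] >= ps[i + 1] for i in range(len(ps) - 1))

    def test_zero_variance_timepoints_warned_and_excluded(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((6, 20))
        data[:, 7] = 3.0  # identical across participants
        with pytest.warns(UserWarning, match="zero-variance"):
            res = inf.cluster_onesample(data, np.arange(20.0), _cfg())
        for c in res.clusters:
            assert not (c.start_index <= 7 <= c.end_index)


class TestPaired:
    def test_identical_conditions_produce_no_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((8, 30))
        res = inf.cluster_paired(a, a.copy(), np.arange(30.0), _cfg())
        assert res.clusters == []

    def test_attenuation_localized_to_window(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((12, 50)) * 0.5
        b = a.copy()
        b[:, 10:25] -= 1.5
        res = inf.cluster_paired(a, b, np.arange(50.0), _cfg(n_iterations=500))
        sig = res.significant()
        assert sig
        for c in sig:
            assert c.start_index >= 9 and c.end_index <= 26
            assert c.sign > 0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((10, 40)) * 0.5
        b = a + 0.0
        b[:, 5:20] += 1.0
        res_ab = inf.cluster_paired(a, b, np.arange(40.0), _cfg())
        res_ba = inf.cluster_paired(b, a, np.arange(40.0), _cfg())
        assert [(c.start_index, c.end_index) for c in res_ab.clusters] == [
            (c.start_index, c.end_index) for c in res_ba.clusters
        ]
        assert [c.sign for c in res_ab.clusters] == [-c.sign for c in res_ba.clusters]


class TestPeak:
    def test_constant_mean_tie_breaks_to_first(self):
        rng = np.random.default_rng(8)
        col = rng.standard_normal(5)
        data = np.tile(col[:, None], (1, 4))  # identical columns: exact tie
        out = inf.peak_statistics(data, np.array([10.0, 20.0, 30.0, 40.0]))
        assert out.time_ms == 10.0

    def test_closed_form_cohens_d(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(16)
        x = (x - x.mean()) / x.std(ddof=1)  # exactly mean 0, sd 1
        data = (0.6 + 0.1 * x)[:, None]
        out = inf.peak_statistics(data, np.array([0.0]), null_value=0.5)
        assert out.cohens_d == pytest.approx(1.0)
        assert out.df == 15

    def test_matches_textbook_t_and_d(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((12, 25)) + 0.3
        out = inf.peak_statistics(data, np.arange(25.0))
        col = data[:, int(out.time_ms)]
        t_ref, _ = stats.ttest_1samp(col, 0.0)
        d_ref = col.mean() / col.std(ddof=1)
        assert out.t_value == pytest.approx(t_ref, abs=1e-12)
        assert out.cohens_d == pytest.approx(d_ref, abs=1e-12)

    def test_peak_restricted_to_significant_clusters(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((10, 50)) * 0.3
        data[:, 10:20] += 1.0
        data[:, 40] += 3.0  # single-sample spike: global max, not a cluster
        res = inf.cluster_onesample(data, np.arange(50.0), _cfg(n_iterations=500))
        sig = [c for c in res.significant() if c.size > 1]
        out = inf.peak_statistics(data, np.arange(50.0), clusters=sig)
        assert 10 <= out.time_ms <= 19


class TestNullAgainstMNE:
    def test_cluster_p_values_consistent_with_mne(self):
        """Cross-check against MNE's one-sample cluster permutation test on a
        shared dataset (both use sign-flip max-cluster null; MNE thresholds
        on t, so the threshold is converted)."""
        import mne.stats

        rng = np.random.default_rng(12)
        data = rng.standard_normal((14, 60)) * 0.8
        data[:, 20:35] += 0.9
        df = data.shape[0] - 1
        cfg = _cfg(n_iterations=2000, seed=0)
        res = inf.cluster_onesample(data, np.arange(60.0), cfg)
        # convert the z threshold back to the equivalent t threshold
        t_thr = stats.t.isf(stats.norm.sf(cfg.z_threshold_one_sided), df)
        _, clusters, pvals, _ = mne.stats.permutation_cluster_1samp_test(
            data, threshold=t_thr, n_permutations=2000, tail=1,
            stat_fun=None, seed=1, out_type="mask", verbose=False,
            t_power=0,  # score clusters by their size, as we do
        )
        mne_sig = {
            (c[0].start, c[0].stop - 1) for c, p in zip(clusters, pvals) if p < 0.05
        }
        ours_sig = {(c.start_index, c.end_index) for c in res.significant()}
        assert ours_sig == mne_sig
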