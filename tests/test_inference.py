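import numpy as np
import pytest

from kurnet.inference import (BandDefinition, ChannelRecording,
                              DirectedFunctionalNetwork, InferenceConfig,
                              LaggedCorrelationMatrix, band_split,
                              directionalize, iaaft_surrogate,
                              infer_functional_network, lagged_crosscorr,
                              lagged_correlation_matrix, preprocess,
                              prune_indirect, significance_mask)
from kurnet.synthetic import gen_lagged_recording, make_lagged_truth


def sine_recording(freqs_hz, fs=256.0, duration=8.0, labels=None):
    t = np.arange(int(fs * duration)) / fs
    data = np.stack([np.sin(2 * np.pi * f * t) for f in freqs_hz])
    labels = labels or [f"ch{i}" for i in range(len(freqs_hz))]
    return ChannelRecording(labels=labels, fs=fs, data=data)


def amplitude(x):
    return np.sqrt(2.0) * np.std(x)


class TestPreprocess:
    def test_passband_tone_preserved(self):
        rec = sine_recording([10.0, 20.0])
        out = preprocess(rec)
        mid = slice(256, -256)   # steady state, past filter edge transients
        assert amplitude(out.data[0, mid]) == pytest.approx(1.0, rel=0.02)

    def test_power_line_tone_removed(self):
        rec = sine_recording([50.0, 10.0])
        out = preprocess(rec)
        mid = slice(256, -256)
        assert amplitude(out.data[0, mid]) < 0.05

    def test_constant_channel_zeroed(self):
        rec = sine_recording([10.0, 12.0])
        rec.data[1] = 3.7
        out = preprocess(rec)
        assert np.max(np.abs(out.data[1])) < 1e-6

    def test_nyquist_violation_rejected(self):
        rec = sine_recording([10.0, 12.0], fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(rec, hi=70.0)


class TestBandSplit:
    def test_theta_tone_kept_in_theta_removed_in_low_alpha(self):
        rec = sine_recording([4.5, 4.5], duration=16.0)
        theta, low_alpha = band_split(rec, [BandDefinition("theta", 3, 6),
                                            BandDefinition("low_alpha", 6, 9)])
        mid = slice(512, -512)   # ignore filter edge transients
        assert amplitude(theta.data[0, mid]) == pytest.approx(1.0, rel=0.05)
        assert amplitude(low_alpha.data[0, mid]) < 0.1
        assert theta.band == "theta" and low_alpha.band == "low_alpha"

    def test_band_variances_sum_to_broadband(self, rng):
        # Parseval with non-overlapping near-brick-wall bands
        from kurnet.inference import DEFAULT_BANDS
        data = rng.standard_normal((2, 8192))
        rec = ChannelRecording(labels=["a", "b"], fs=256.0, data=data)
        broad = preprocess(rec, notch=None)
        parts = band_split(broad, DEFAULT_BANDS)
        total = sum(p.data[0].var() for p in parts)
        assert total == pytest.approx(broad.data[0].var(), rel=0.15)

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 6, 6)


class TestLaggedCrosscorr:
    def test_exact_shift_recovered_with_leading_sign(self, rng):
        x = rng.standard_normal(2000)
        y = np.concatenate([rng.standard_normal(5), x[:-5]])  # y = x delayed 5
        c, lag = lagged_crosscorr(x, y, 50)
        assert lag == 5 and abs(c) > 0.99

    def test_self_correlation_is_one_at_zero_lag(self, rng):
        x = rng.standard_normal(1000)
        c, lag = lagged_crosscorr(x, x, 30)
        assert c == pytest.approx(1.0, abs=1e-12) and lag == 0

    def test_independent_noise_stays_low(self, rng):
        hits = 0
        for _ in range(10):
            a = rng.standard_normal(5120)
            b = rng.standard_normal(5120)
            c, _ = lagged_crosscorr(a, b, 51)
            hits += abs(c) >= 0.1
        assert hits == 0

    def test_every_lag_value_is_normalized(self, rng):
        # overlapping-window normalization keeps each lag in [-1, 1]
        from kurnet.inference import _PreparedSeries, _corr_all_lags
        x = np.cumsum(rng.standard_normal(512))   # strong autocorrelation
        y = np.cumsum(rng.standard_normal(512))
        nfft = 2048
        lags, c = _corr_all_lags(_PreparedSeries(x, nfft),
                                 _PreparedSeries(y, nfft), 100)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)

    def test_matches_direct_windowed_pearson(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        from kurnet.inference import _PreparedSeries, _corr_all_lags
        lags, c = _corr_all_lags(_PreparedSeries(x, 1024),
                                 _PreparedSeries(y, 1024), 7)
        for tau, got in zip(lags, c):
            u = x[:300 - tau] if tau >= 0 else x[-tau:]
            v = y[tau:] if tau >= 0 else y[:300 + tau]
            assert got == pytest.approx(np.corrcoef(u, v)[0, 1], abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            lagged_crosscorr(np.ones(100), np.arange(100.0), 10)


class TestIaaft:
    def test_value_multiset_preserved_exactly(self, rng):
        x = rng.standard_normal(512)
        s = iaaft_surrogate(x, n_iter=20, seed=0)
        assert np.array_equal(np.sort(s), np.sort(x))
        assert not np.array_equal(s, x)

    def test_spectrum_match_on_ar1(self, rng):
        from scipy import signal as sps
        e = rng.standard_normal(5320)
        x = sps.lfilter([1.0], [1.0, -0.95], e)[200:]
        s = iaaft_surrogate(x, n_iter=100, seed=1)
        p0 = np.abs(np.fft.rfft(x)) ** 2
        p1 = np.abs(np.fft.rfft(s)) ** 2
        assert np.linalg.norm(p1 - p0) / np.linalg.norm(p0) < 0.01

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(256)
        assert np.array_equal(iaaft_surrogate(x, 10, seed=5),
                              iaaft_surrogate(x, 10, seed=5))

    def test_surrogates_destroy_cross_correlation(self, rng):
        # genuinely coupled channels: surrogate pair correlation collapses
        # to the level of independent series
        x = rng.standard_normal(2048)
        y = 0.9 * np.concatenate([rng.standard_normal(8), x[:-8]])
        y += 0.4 * rng.standard_normal(2048)
        c_obs, _ = lagged_crosscorr(x, y, 40)
        nulls = [abs(lagged_crosscorr(iaaft_surrogate(x, 20, seed=k),
                                      iaaft_surrogate(y, 20, seed=100 + k),
                                      40)[0]) for k in range(10)]
        assert abs(c_obs) > 0.8
        assert max(nulls) < 0.2

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            iaaft_surrogate(np.arange(8.0), 10, seed=0)
        with pytest.raises(ValueError):
            iaaft_surrogate(np.arange(100.0), 0, seed=0)


class TestSignificanceMask:
    def test_trivial_keep_and_remove(self, rng):
        # a pair far above every surrogate is kept; an exact-duplicate null
        # pair is removed
        truth = make_lagged_truth(n_channels=4, n_edges=1, duration=8.0,
                                  seed=2)
        rec = gen_lagged_recording(truth, seed=2)
        lcm = lagged_correlation_matrix(rec, 20)
        keep = significance_mask(lcm, rec, n_surrogates=19, alpha=0.05,
                                 seed=0, n_iter=20)
        i, j = np.argwhere(truth.true_adjacency > 0)[0]
        assert keep[i, j]
        assert keep.sum(axis=None) <= 2 * 3   # few pairs survive

    def test_insufficient_surrogates_rejected(self, rng):
        truth = make_lagged_truth(n_channels=3, n_edges=1, duration=4.0,
                                  seed=0)
        rec = gen_lagged_recording(truth, seed=0)
        lcm = lagged_correlation_matrix(rec, 10)
        with pytest.raises(ValueError, match="n_surrogates"):
            significance_mask(lcm, rec, n_surrogates=10, alpha=0.05, seed=0)


class TestDirectionalize:
    def make_lcm(self, corr, lag, labels):
        return LaggedCorrelationMatrix(corr=np.asarray(corr, float),
                                       lag=np.asarray(lag), max_lag=10,
                                       labels=labels)

    def test_positive_lag_assigns_source_role(self):
        corr = [[1.0, 0.8], [0.8, 1.0]]
        lag = [[0, 5], [-5, 0]]      # channel 0 leads channel 1
        net = directionalize(self.make_lcm(corr, lag, ["a", "b"]),
                             np.array([[False, True], [True, False]]))
        assert net.weights[1, 0] == 0.8   # edge a -> b (row = receiver)
        assert net.weights[0, 1] == 0.0

    def test_zero_lag_pair_removed(self):
        corr = [[1.0, 0.9], [0.9, 1.0]]
        lag = [[0, 0], [0, 0]]
        net = directionalize(self.make_lcm(corr, lag, ["a", "b"]),
                             np.array([[False, True], [True, False]]))
        assert net.n_edges == 0
        assert net.provenance["zero_lag_removed"] == 1

    def test_duplicate_channel_yields_no_edge(self, rng):
        # exact copy at zero shift: volume-conduction-style instantaneous
        # correlation must not become a directed edge
        x = rng.standard_normal(1024)
        z = rng.standard_normal(1024)
        rec = ChannelRecording(labels=["a", "b", "c"], fs=128.0,
                               data=np.stack([x, x.copy(), z]))
        lcm = lagged_correlation_matrix(rec, 20)
        mask = np.ones((3, 3), bool)
        net = directionalize(lcm, mask)
        assert net.weights[0, 1] == 0.0 and net.weights[1, 0] == 0.0


class TestPruneIndirect:
    def edge_net(self, edges, n=4):
        w = np.zeros((n, n))
        for s, t, weight in edges:
            w[t, s] = weight
        return DirectedFunctionalNetwork(weights=w,
                                         labels=[str(i) for i in range(n)])

    def test_weaker_direct_edge_removed_first_order(self):
        net = self.edge_net([(0, 1, 0.5), (0, 2, 0.8), (2, 1, 0.7)])
        out = prune_indirect(net)
        assert out.weights[1, 0] == 0.0          # a->b gone
        assert out.weights[2, 0] == 0.8 and out.weights[1, 2] == 0.7
        assert out.provenance["pruned_first_order"] == 1

    def test_strongest_direct_edge_kept(self):
        net = self.edge_net([(0, 1, 0.9), (0, 2, 0.8), (2, 1, 0.7)])
        out = prune_indirect(net)
        assert out.n_edges == 3

    def test_second_order_chain_removal(self):
        net = self.edge_net([(0, 1, 0.9), (1, 2, 0.9), (2, 3, 0.9),
                             (0, 3, 0.3)])
        out = prune_indirect(net)
        assert out.weights[3, 0] == 0.0
        assert out.provenance["pruned_second_order"] == 1

    def test_never_adds_edges_and_idempotent(self, rng):
        for trial in range(20):
            n = 6
            w = np.triu(rng.uniform(0, 1, (n, n)) *
                        (rng.random((n, n)) < 0.5), 1)
            net = DirectedFunctionalNetwork(weights=w.T,
                                            labels=[str(i) for i in range(n)])
            once = prune_indirect(net)
            twice = prune_indirect(once)
            assert once.n_edges <= net.n_edges
            assert np.array_equal(once.weights, twice.weights)

    def test_product_path_strength_option(self):
        # with the product rule a 0.8*0.7 = 0.56 path beats a 0.5 edge
        net = self.edge_net([(0, 1, 0.5), (0, 2, 0.8), (2, 1, 0.7)])
        out = prune_indirect(net, path_op="product")
        assert out.weights[1, 0] == 0.0


class TestEndToEnd:
    def test_pipeline_deterministic(self):
        truth = make_lagged_truth(n_channels=5, n_edges=2, duration=6.0,
                                  seed=4)
        rec = gen_lagged_recording(truth, seed=4)
        cfg = InferenceConfig(n_surrogates=19, alpha=0.05, iaaft_iters=15)
        n1 = infer_functional_network(rec, band=None, config=cfg, seed=9)
        n2 = infer_functional_network(rec, band=None, config=cfg, seed=9)
        assert np.array_equal(n1.weights, n2.weights)

    def test_antisymmetry_and_label_preservation(self):
        truth = make_lagged_truth(n_channels=6, n_edges=3, duration=6.0,
                                  seed=6)
        rec = gen_lagged_recording(truth, seed=6)
        cfg = InferenceConfig(n_surrogates=19, alpha=0.05, iaaft_iters=15)
        net = infer_functional_network(rec, band=None, config=cfg, seed=1)
        assert not np.any((net.weights > 0) & (net.weights.T > 0))
        assert net.labels == rec.labels

    def test_planted_edges_recovered_small(self):
        truth = make_lagged_truth(n_channels=6, n_edges=3, duration=10.0,
                                  seed=8)
        rec = gen_lagged_recording(truth, seed=8)
        cfg = InferenceConfig(n_surrogates=39, alpha=0.025, iaaft_iters=30)
        net = infer_functional_network(rec, band=None, config=cfg, seed=2)
        true_edges = {(s, t) for t, s in zip(*np.nonzero(truth.true_adjacency))}
        est_edges = {(s, t) for t, s in zip(*np.nonzero(net.weights))}
        assert len(true_edges & est_edges) >= 2


class TestNetworkIO:
    def test_csv_roundtrip_preserves_labels(self, tmp_path, rng):
        w = np.zeros((3, 3))
        w[1, 0] = 0.4
        net = DirectedFunctionalNetwork(weights=w, labels=["F7", "Fp1", "Cz"],
                                        band="theta")
        net.to_csv(tmp_path / "n.csv")
        back = DirectedFunctionalNetwork.from_csv(tmp_path / "n.csv",
                                                  band="theta")
        assert back.labels == ["F7", "Fp1", "Cz"]
        assert np.allclose(back.weights, w)

    def test_recording_csv_roundtrip(self, tmp_path, rng):
        rec = ChannelRecording(labels=["a", "b"], fs=128.0,
                               data=rng.standard_normal((2, 64)))
        rec.to_csv(tmp_path / "r.csv")
        back = ChannelRecording.from_csv(tmp_path / "r.csv")
        assert back.fs == pytest.approx(128.0)
        assert np.allclose(back.data, rec.data)
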