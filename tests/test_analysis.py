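"""Population analysis: PSTH binning, cosine correlations, distances,
complexity, optimization surface, histograms and PC trajectories."""
import numpy as np
import pytest

from alnet.analysis import (
    bin_windows, complexity_per_pn, compute_psth, cosine_correlation,
    euclidean_distance_series, odor_pair_correlations,
    onset_correlation_series, optimization_surface, response_histogram,
    stimulus_window_counts, trajectory_summary, trial_correlations,
    window_bins, onset_bin,
)
from alnet.raster import SpikeRaster


def _raster(n, times_by_neuron, length=3000.0, **meta):
    ids, ts = [], []
    for i, ts_i in times_by_neuron.items():
        ids.extend([i] * len(ts_i))
        ts.extend(ts_i)
    return SpikeRaster(n, length, np.array(ids, dtype=int),
                       np.array(ts, dtype=float), dict(meta))


class TestPSTH:
    def test_empty_raster_gives_300_by_120_zeros(self):
        mat = compute_psth(_raster(300, {}))
        assert mat.shape == (300, 120)
        assert mat.sum() == 0

    def test_single_spike_falls_in_two_covering_bins(self):
        mat = compute_psth(_raster(300, {7: [1000.0]}))
        cols = np.flatnonzero(mat[7])
        w = bin_windows(3000.0)
        assert list(cols) == [39, 40]
        for k in cols:
            assert w[k, 0] <= 1000.0 < w[k, 1]
        assert mat.sum() == 2

    def test_counts_match_brute_force_recount(self, rng):
        times = {i: np.sort(rng.uniform(0, 3000, rng.integers(0, 30)))
                 for i in range(20)}
        ras = _raster(20, times)
        mat = compute_psth(ras)
        w = bin_windows(3000.0)
        brute = np.zeros_like(mat)
        for i, ts in times.items():
            for t in ts:
                for k, (a, b) in enumerate(w):
                    if a <= t < a + 50.0:    # untruncated window covers t
                        brute[i, k] += 1
        assert np.array_equal(mat, brute)
        assert mat.sum() <= 2 * ras.n_spikes

    def test_out_of_bounds_spike_rejected(self):
        with pytest.raises(ValueError):
            SpikeRaster(10, 3000.0, np.array([0]), np.array([3500.0]))

    def test_window_and_onset_bins(self):
        bins = window_bins(3000.0, 500.0, 1500.0)
        assert bins[0] == 19 and bins[-1] == 59
        assert onset_bin(3000.0, 500.0) == 19


class TestCosine:
    def test_identical_nonzero_vectors(self):
        v = np.array([1.0, 2.0, 0.0])
        assert cosine_correlation(v, v) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert cosine_correlation([1, 0, 0], [0, 2, 0]) == 0.0

    def test_scale_invariance(self):
        u = np.array([1.0, 3.0, 2.0])
        assert cosine_correlation(u, 3 * u) == pytest.approx(1.0)

    def test_zero_vector_conventions(self):
        z = np.zeros(4)
        assert cosine_correlation(z, z) == 1.0
        assert cosine_correlation(z, np.ones(4)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_correlation([1, 2], [1, 2, 3])


class TestOnsetSeries:
    def test_constant_activity_flat_at_one(self):
        mat = np.ones((30, 120))
        series = onset_correlation_series(mat, 3000.0)
        assert np.allclose(series, 1.0)

    def test_rotating_active_set_decreases_monotonically(self):
        """Indicator set rotating one neuron per bin: overlap shrinks as
        (w - k)/w, so the series decreases until disjoint."""
        n, w, nb = 200, 40, 120
        mat = np.zeros((n, nb))
        for k in range(nb):
            mat[(np.arange(w) + k) % n, k] = 1.0
        series = onset_correlation_series(mat, 3000.0)
        expect = np.maximum(w - np.arange(len(series)), 0) / w
        assert np.allclose(series, expect)
        assert np.all(np.diff(series[:w]) < 0)


class TestPairCorrelations:
    def test_identical_responses_all_one(self, rng):
        base = rng.poisson(2.0, size=(30, 120)).astype(float)
        stack = np.stack([base] * 5)
        out = odor_pair_correlations(stack, 3000.0, [(0, 1), (1, 2)])
        assert np.allclose(out["matrices"], 1.0)
        assert out["C_odors"] == pytest.approx(1.0)

    def test_diagonal_is_one_every_bin(self, rng):
        stack = rng.poisson(1.0, size=(4, 20, 120)).astype(float)
        out = odor_pair_correlations(stack, 3000.0, [(0, 1)])
        mats = out["matrices"]
        for k in range(mats.shape[0]):
            assert np.allclose(np.diag(mats[k]), 1.0)
            assert np.allclose(mats[k], mats[k].T)
            assert mats[k].min() >= 0.0 and mats[k].max() <= 1.0

    def test_trial_correlation_mean_matches_brute_force(self, rng):
        stack = rng.poisson(2.0, size=(10, 15, 120)).astype(float)
        out = trial_correlations(stack, 3000.0)
        mats = out["matrices"]
        k = 30
        vals = [cosine_correlation(stack[i, :, k], stack[j, :, k])
                for i in range(10) for j in range(i + 1, 10)]
        assert len(vals) == 45
        assert out["series"][k] == pytest.approx(np.mean(vals))
        assert np.allclose(mats[k][np.triu_indices(10, 1)],
                           [cosine_correlation(stack[i, :, k], stack[j, :, k])
                            for i in range(10) for j in range(i + 1, 10)])

    def test_identical_trials_give_c_trials_one(self, rng):
        base = rng.poisson(2.0, size=(20, 120)).astype(float)
        out = trial_correlations(np.stack([base] * 6), 3000.0)
        assert out["C_trials"] == pytest.approx(1.0)


class TestDistance:
    def test_identical_zero_everywhere(self, rng):
        a = rng.poisson(1.0, size=(30, 120)).astype(float)
        out = euclidean_distance_series(a, a, 3000.0)
        assert np.all(out["series"] == 0)

    def test_scaling_changes_distance_not_cosine(self, rng):
        a = rng.poisson(2.0, size=(30, 120)).astype(float) + 1
        b = 2 * a
        d = euclidean_distance_series(a, b, 3000.0)["series"]
        assert np.all(d > 0)
        assert cosine_correlation(a[:, 10], b[:, 10]) == pytest.approx(1.0)

    def test_stimulus_mean_matches_brute_force(self, rng):
        a = rng.poisson(2.0, size=(30, 120)).astype(float)
        b = rng.poisson(2.0, size=(30, 120)).astype(float)
        out = euclidean_distance_series(a, b, 3000.0)
        bins = window_bins(3000.0, 500.0, 1500.0)
        brute = np.mean([np.linalg.norm(a[:, k] - b[:, k]) for k in bins])
        assert out["stimulus_mean"] == pytest.approx(brute)


class TestComplexity:
    def test_static_response_has_zero_complexity(self):
        assert complexity_per_pn(np.full((21, 20), 3.0)) == 0

    def test_rank_one_response_has_complexity_one(self):
        u = np.arange(21.0)[:, None]
        t = np.sin(np.linspace(0, 3, 20))[None, :]
        assert complexity_per_pn(u * t + 5.0) == 1

    def test_matches_eigendecomposition_oracle(self, rng):
        """Count eigenvalues of the time-covariance reaching 80% variance."""
        for _ in range(20):
            x = rng.normal(size=(21, 20))
            xc = x - x.mean(axis=1, keepdims=True)
            ev = np.sort(np.linalg.eigvalsh(xc @ xc.T))[::-1]
            frac = np.cumsum(ev) / ev.sum()
            brute = int(np.searchsorted(frac, 0.8 - 1e-12) + 1)
            got = complexity_per_pn(x)
            assert got == brute
            assert 1 <= got <= 20
            assert np.all(np.diff(frac) >= -1e-12)

    def test_stimulus_window_counts_shape(self):
        ras = _raster(10, {3: [600.0, 700.0, 1499.0], 5: [200.0]})
        cnt = stimulus_window_counts(ras)
        assert cnt.shape == (10, 20)
        assert cnt[3].sum() == 3
        assert cnt[5].sum() == 0


class TestSurfaceAndHistogram:
    def test_surface_extremes(self):
        out = optimization_surface(np.array([[1.0]]), np.array([[0.0]]))
        assert out["M"][0, 0] == 2.0
        c = np.array([[0.3, 0.7], [0.5, 0.9]])
        assert np.allclose(optimization_surface(c, c)["M"], 1.0)

    def test_argmax_matches_brute_force(self, rng):
        ct = rng.random((6, 6))
        co = rng.random((6, 6))
        out = optimization_surface(ct, co)
        m = ct + 1 - co
        brute = max(((i, j) for i in range(6) for j in range(6)),
                    key=lambda ij: m[ij])
        assert out["argmax"] == brute

    def test_surface_invariant_to_odor_relabeling(self, rng):
        """M depends on pair averages, not on odor identity order."""
        stack = rng.poisson(2.0, size=(5, 20, 120)).astype(float)
        pairs = [(0, 1), (2, 3)]
        out1 = odor_pair_correlations(stack, 3000.0, pairs)["C_odors"]
        perm = [4, 3, 2, 1, 0]
        inv = {o: i for i, o in enumerate(perm)}
        pairs2 = [tuple(sorted((inv[a], inv[b]))) for a, b in pairs]
        out2 = odor_pair_correlations(stack[perm], 3000.0, pairs2)["C_odors"]
        assert out1 == pytest.approx(out2)

    def test_empty_rasters_concentrate_at_zero(self):
        out = response_histogram([_raster(50, {}) for _ in range(3)])
        assert out["proportion"][0] == 1.0

    def test_proportions_sum_to_one_and_match_tally(self, rng):
        rasters = []
        for t in range(4):
            times = {i: list(rng.uniform(500, 1500, rng.integers(0, 8)))
                     for i in range(30)}
            rasters.append(_raster(30, times))
        out = response_histogram(rasters)
        assert out["proportion"].sum() == pytest.approx(1.0)
        tally = np.concatenate([r.counts(500.0, 1500.0) for r in rasters])
        for k, p in zip(out["counts"], out["proportion"]):
            assert p == pytest.approx(np.mean(tally == k))


class TestTrajectory:
    def test_normalized_amplitude_peaks_at_one(self, rng):
        base = rng.poisson(1.0, size=(40, 120)).astype(float)
        base[:, 20:60] += rng.poisson(4.0, size=(40, 40))
        out = trajectory_summary(base, 3000.0)
        assert out["normalized_amplitude"].max() == pytest.approx(1.0)
        assert out["pcs"].shape[0] == 3
        assert 0 <= out["time_to_max_ms"] <= 3000.0


class TestEndToEndDecorrelation:
    def test_engineered_rotation_is_detected(self):
        """Similar responses whose active sets rotate over the stimulus:
        correlation falls while distance grows — the machinery detects
        engineered decorrelation."""
        n, nb = 100, 120
        bins = window_bins(3000.0, 500.0, 1500.0)
        a = np.zeros((n, nb))
        b = np.zeros((n, nb))
        for pos, k in enumerate(bins):
            a[(np.arange(20) + pos) % n, k] = 4.0
            b[(np.arange(20) + 3 + 2 * pos) % n, k] = 4.0
        stack = np.stack([a, b])
        out = odor_pair_correlations(stack, 3000.0, [(0, 1)])
        series = out["similar_series"][bins]
        dist = euclidean_distance_series(a, b, 3000.0)["series"][bins]
        assert series[-1] < series[0]
        assert dist[-1] > dist[0]
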