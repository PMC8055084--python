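"""Time-resolved/spatial decoding, CVCR, cluster inference, latencies."""

import numpy as np
import pytest

from freqtrack import (ForwardModel, bootstrap_latency_difference,
                       cluster_permutation_space, cluster_permutation_time,
                       cvcr_regress_out, estimate_peak_latency,
                       generate_session, sensor_adjacency, simulate_recording,
                       timeresolved_decode)
from freqtrack.decoding import _decode_features

LAGS = np.arange(0.0, 901.0, 25.0)


@pytest.fixture(scope="module")
def clean_u_recording(small_session):
    """Noise-free recording encoding only u with a 400-ms kernel."""
    fwd = ForwardModel(n_locations=6, srate=300.0, latency_u=0.4,
                       amp_p=0.0, noise_sd=0.0, pink_sd=0.0, seed=2)
    return simulate_recording(small_session, fwd, tmin=0.0, tmax=6.0,
                              conditions=[("P", "large")])


class TestTimeResolvedDecode:
    def test_zero_noise_latency_recovery(self, clean_u_recording):
        course = timeresolved_decode(clean_u_recording, "u", lags_ms=LAGS,
                                     n_pca=10)
        peak = course.lags_ms[np.argmax(course.r)]
        assert abs(peak - 400.0) <= 25.0  # within one lag step

    def test_noise_only_chance_level(self, small_session):
        fwd = ForwardModel(n_locations=6, srate=300.0, amp_p=0.0, amp_u=0.0,
                           noise_sd=1.0, pink_sd=0.0, seed=3)
        rec = simulate_recording(small_session, fwd, tmin=0.0, tmax=6.0,
                                 conditions=[("U", "large")])
        course = timeresolved_decode(rec, "u", lags_ms=LAGS[::3], n_pca=10)
        assert np.all(np.abs(course.r) < 2 / np.sqrt(course.n_trials))

    def test_scale_invariance(self, clean_u_recording):
        import copy
        a = timeresolved_decode(clean_u_recording, "u", lags_ms=LAGS[8:12],
                                n_pca=6)
        scaled = copy.copy(clean_u_recording)
        scaled.data = 3.7 * clean_u_recording.data
        b = timeresolved_decode(scaled, "u", lags_ms=LAGS[8:12], n_pca=6)
        assert np.allclose(a.r, b.r, atol=1e-10)

    def test_periodic_variable_warns(self, clean_u_recording):
        with pytest.warns(RuntimeWarning, match="autocorrelation"):
            timeresolved_decode(clean_u_recording, "p", lags_ms=LAGS[:2],
                                n_pca=6)

    def test_too_few_trials_rejected(self, clean_u_recording):
        import copy
        rec = copy.copy(clean_u_recording)
        rec.data = rec.data[:2]
        rec.displays = rec.displays[rec.displays["epoch"] < 2]
        rec.trials = rec.trials.iloc[:2]
        with pytest.raises(ValueError):
            timeresolved_decode(rec, "u", lags_ms=LAGS[:2], n_pca=6)

    def test_ols_equivalence_oracle(self, rng):
        """Two channels, one component, vanishing ridge: the decoder matches
        an explicit closed-form OLS pipeline to 1e-8."""
        n_tr, n_disp = 5, 30
        trial_ids = np.repeat(np.arange(n_tr), n_disp)
        X = rng.standard_normal((n_tr * n_disp, 2))
        y = 0.8 * X[:, 0] - 0.3 * X[:, 1] + 0.1 * rng.standard_normal(len(X))
        r_pkg, _ = _decode_features(X, y, trial_ids, n_pca=1, ridge=1e-12)

        rs = []
        for t in range(n_tr):
            te, tr = trial_ids == t, trial_ids != t
            mu, sd = X[tr].mean(0), X[tr].std(0)
            Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
            evals, evecs = np.linalg.eigh(Xtr.T @ Xtr / len(Xtr))
            v = evecs[:, [np.argmax(evals)]]
            ztr, zte = Xtr @ v, Xte @ v
            ys = (y[tr] - y[tr].mean()) / y[tr].std()
            w = np.linalg.lstsq(ztr, ys, rcond=None)[0]
            pred = (zte @ w).ravel()
            a, b = pred - pred.mean(), y[te] - y[te].mean()
            rs.append(a @ b / np.sqrt((a ** 2).sum() * (b ** 2).sum()))
        assert r_pkg == pytest.approx(np.mean(rs), abs=1e-8)


class TestClusterInference:
    def test_no_clusters_on_null(self):
        r = np.zeros((6, 20))
        res = cluster_permutation_time(r, np.arange(20) * 10.0, n_perm=100)
        assert res["clusters"] == []

    def test_two_bands(self):
        rng = np.random.default_rng(21)
        lags = np.arange(40) * 25.0
        # off-band lags sit slightly below zero so only the injected bands
        # can cross the one-sided threshold
        r = 0.02 * rng.standard_normal((10, 40)) - 0.05
        r[:, 5:9] += 0.55    # short band
        r[:, 20:30] += 0.85  # long, stronger band
        res = cluster_permutation_time(r, lags, n_perm=200, rng_seed=0)
        assert len(res["clusters"]) == 2
        sums = [c["sum_t"] for c in res["clusters"]]
        spans = [(c["start_ms"], c["end_ms"]) for c in res["clusters"]]
        assert spans[1][0] == 500.0 and sums[1] > sums[0]
        # the sign-flip null keeps the real effect under partial flips, so
        # the floor 1/(n_perm+1) is not always reached; clearly significant
        assert res["clusters"][1]["p"] < 0.05
        assert res["method"] == "signflip-surrogate"

    def test_needs_multiple_subjects(self):
        with pytest.raises(ValueError):
            cluster_permutation_time(np.zeros((1, 10)), np.arange(10.0))


class TestPeakLatency:
    def test_single_lag_centroid(self):
        lags = np.arange(0, 1000, 100.0)
        t = np.zeros(10)
        t[3] = 5.0
        lat = estimate_peak_latency(lags, t, [{"lags_idx": np.array([3])}])
        assert lat == 300.0

    def test_symmetric_profile_centroid(self):
        lags = np.arange(0, 901, 20.0)
        t = np.zeros(len(lags))
        run = np.arange(15, 26)  # 300..500 ms, symmetric around 400
        t[run] = 5.0 - np.abs(np.arange(-5, 6))
        lat = estimate_peak_latency(lags, t, [{"lags_idx": run}])
        assert lat == pytest.approx(400.0)

    def test_no_cluster_in_window(self):
        lags = np.arange(0, 1000, 100.0)
        t = np.ones(10)
        assert estimate_peak_latency(lags, t, [{"lags_idx": np.array([7])}],
                                     window=(100, 500)) is None


class TestBootstrapLatency:
    def test_identical_vectors(self):
        lat = np.array([300.0, 320.0, 340.0, 310.0])
        diff, ci = bootstrap_latency_difference(lat, lat)
        assert diff == 0.0 and ci == (0.0, 0.0)

    def test_constant_offset(self):
        lat = np.array([300.0, 320.0, 340.0, 310.0])
        diff, ci = bootstrap_latency_difference(lat, lat + 100.0, rng_seed=0)
        assert diff == pytest.approx(100.0)
        assert ci == (pytest.approx(100.0), pytest.approx(100.0))

    def test_coverage(self):
        rng = np.random.default_rng(77)
        hits = 0
        for rep in range(60):
            lp = 300 + 40 * rng.standard_normal(8)
            lu = lp + 100 + 40 * rng.standard_normal(8)
            _, (lo, hi) = bootstrap_latency_difference(lp, lu, n_boot=300,
                                                       rng_seed=rep)
            hits += lo <= 100 <= hi
        assert hits >= 48  # ~95% nominal coverage, small-sample slack

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            bootstrap_latency_difference([1.0, 2.0], [1.0, 2.0])


class TestCvcr:
    def test_constant_column_dropped(self, rng):
        feats = rng.standard_normal((60, 4))
        conf = rng.standard_normal((60, 2))
        conf_aug = np.column_stack([conf, np.full(60, 3.3)])  # constant col
        folds = [(np.arange(30), np.arange(30, 60)),
                 (np.arange(30, 60), np.arange(30))]
        with pytest.warns(RuntimeWarning, match="collinear"):
            out_aug = cvcr_regress_out(feats, conf_aug, folds)
        out = cvcr_regress_out(feats, conf, folds)
        assert np.allclose(out, out_aug)

    def test_removes_confound_signal(self, rng):
        conf = rng.standard_normal((80, 1))
        feats = conf @ rng.standard_normal((1, 5))  # purely confound-driven
        folds = [(np.arange(40), np.arange(40, 80)),
                 (np.arange(40, 80), np.arange(40))]
        out = cvcr_regress_out(feats, conf, folds)
        assert np.max(np.abs(out)) < 0.2 * np.max(np.abs(feats))

    def test_confound_only_signal_decodes_at_chance_after_cvcr(self):
        """A recording driven purely by display confounds decodes the
        numerosity strongly; after CVCR with N in the design it is chance."""
        session = generate_session("c", {"formal_per_condition": 8,
                                         "catch_per_condition": 0,
                                         "n_blocks": 1}, rng_seed=9)
        fwd = ForwardModel(n_locations=6, srate=300.0, amp_p=0.0, amp_u=0.0,
                           amp_conf=3.0, noise_sd=0.05, pink_sd=0.0, seed=4)
        rec = simulate_recording(session, fwd, encode_confounds=True,
                                 tmin=0.0, tmax=6.0,
                                 conditions=[("U", "large")])
        lags = np.arange(100.0, 301.0, 50.0)
        raw = timeresolved_decode(rec, "N", lags_ms=lags, n_pca=6)
        regressed = timeresolved_decode(rec, "N", lags_ms=lags, n_pca=6,
                                        confounds=["N", "Nt", "No", "vCIE_a",
                                                   "vCIE_b", "AvgLumi"])
        assert raw.r.max() > 0.5
        # chance band for 8 trials x 40-display sequences
        assert np.all(np.abs(regressed.r) < 0.3)
        assert regressed.r.max() < raw.r.max() - 0.3


class TestSpatialInference:
    def test_adjacency_threshold(self):
        loc = np.array([[0.0, 0, 0], [0.03, 0, 0], [0.2, 0, 0]])
        adj = sensor_adjacency(loc, threshold=0.04)
        assert adj[0, 1] and not adj[0, 2] and not adj[0, 0]

    def test_degenerate_adjacency_each_location_own_cluster(self, rng):
        r = 0.05 * rng.standard_normal((8, 6)) + 0.4
        adj = np.zeros((6, 6), dtype=bool)
        res = cluster_permutation_space(r, adj, n_perm=100, rng_seed=0)
        assert all(len(c["locations"]) == 1 for c in res["clusters"])
        assert len(res["clusters"]) == 6

    def test_localized_signal_found(self):
        rng = np.random.default_rng(31)
        # strong decoding at 4 adjacent locations out of 10
        loc = np.column_stack([np.linspace(0, 0.27, 10), np.zeros(10),
                               np.zeros(10)])
        adj = sensor_adjacency(loc, threshold=0.04)
        r = 0.05 * rng.standard_normal((8, 10))
        r[:, 3:7] += 0.5
        res = cluster_permutation_space(r, adj, n_perm=200, rng_seed=1)
        sig = [c for c in res["clusters"] if c["p"] < 0.05]
        assert len(sig) == 1
        assert set(sig[0]["locations"]) == {3, 4, 5, 6}
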