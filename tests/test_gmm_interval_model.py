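"""Second-order interval mixture: preprocessing, EM, sampling, surrogates."""

import numpy as np
import pytest
from scipy import stats

from flyephys import _mixture, synthgen
from flyephys.gmm_interval_model import (
    BetaRateModel,
    SecondOrderIntervalModel,
    SecondOrderIntervalResults,
    binarize,
    fit_gmm,
    preprocess_pairs,
)


class TestPreprocess:
    def test_constant_intervals_collapse_to_origin(self):
        pd_ = preprocess_pairs([np.full(50, 0.2)])
        np.testing.assert_allclose(pd_.pairs, 0.0, atol=1e-12)
        assert pd_.histogram.sum() == 49

    def test_histogram_conserves_pairs_inside_range(self):
        rng = np.random.default_rng(0)
        ivals = rng.lognormal(-1.5, 0.5, size=500)
        pd_ = preprocess_pairs([ivals])
        assert pd_.pairs.shape[0] == 499
        assert pd_.histogram.shape == (22, 22)
        assert pd_.histogram.sum() <= 499  # percentile range clips tails only

    def test_rate_normalization_makes_cells_comparable(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0.0, 0.3, size=300)
        fast = base / 10.0  # same structure, 10x the rate
        p1 = preprocess_pairs([base])
        p2 = preprocess_pairs([fast])
        np.testing.assert_allclose(p1.pairs, p2.pairs, atol=1e-12)

    def test_short_cells_skipped(self):
        pd_ = preprocess_pairs([np.full(50, 0.2), np.array([0.1])])
        assert pd_.n_cells_used == 1 and pd_.n_cells_skipped == 1
        with pytest.raises(ValueError):
            preprocess_pairs([np.array([0.1])])


class TestEm:
    def test_loglik_nondecreasing_and_weights_simplex(self, fitted_results):
        res = fitted_results
        assert np.all(np.diff(res.loglik_path) >= -1e-12)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_planted_means(self, three_cluster_spec, fitted_results):
        w, mu, cov = three_cluster_spec.arrays()
        shift = np.log(three_cluster_spec.mean_normalized_interval())
        planted = mu - shift  # rate normalization shifts log intervals by log(m)
        order = np.argsort(planted[:, 0])
        rec = fitted_results.means[np.argsort(fitted_results.means[:, 0])]
        assert np.abs(rec - planted[order]).max() < 0.1

    def test_bic_selects_single_component_for_spherical_data(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pairs = rng.normal(size=(2000, 2)) * 0.5
            res = fit_gmm(pairs, k_range=(1, 2, 3), seed=seed, n_restarts=1)
            hits += res.n_components == 1
        assert hits >= 19

    def test_agrees_with_sklearn_reference(self, fitted_results):
        sklearn = pytest.importorskip("sklearn.mixture")
        gm = sklearn.GaussianMixture(
            n_components=3, covariance_type="full", n_init=3, random_state=0, tol=1e-6
        ).fit(fitted_results.training_pairs)
        ours = fitted_results.means[np.argsort(fitted_results.means[:, 0])]
        ref = gm.means_[np.argsort(gm.means_[:, 0])]
        assert np.abs(ours - ref).max() < 0.02

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            fit_gmm(np.zeros((20, 2)), k_range=(3,))


class TestSampling:
    def test_validation_sample_is_size_matched_and_plausible(self, fitted_results):
        report = fitted_results.sample_validation(seed=1)
        assert report["n"] == fitted_results.n_obs
        assert report["ks_x_pvalue"] > 0.01 and report["ks_y_pvalue"] > 0.01

    def test_sample_mean_matches_mixture_moments(self, fitted_results):
        n = 20_000
        sample = fitted_results.sample_pairs(n=n, seed=2)
        mean_th = (fitted_results.weights[:, None] * fitted_results.means).sum(axis=0)
        var_th = (
            fitted_results.weights[:, None]
            * (
                np.stack([np.diag(c) for c in fitted_results.covariances])
                + fitted_results.means**2
            )
        ).sum(axis=0) - mean_th**2
        se = np.sqrt(var_th / n)
        assert np.all(np.abs(sample.mean(axis=0) - mean_th) < 3 * se)

    def test_rejection_matches_exact_conditional_at_fixed_x(self, fitted_results):
        w, mu, cov = (
            fitted_results.weights,
            fitted_results.means,
            fitted_results.covariances,
        )
        y_range = fitted_results.proposal_range_y()
        n = 4000
        passes = 0
        for seed in range(5):
            r1 = np.random.default_rng(seed)
            r2 = np.random.default_rng(500 + seed)
            wc, mc, vc = _mixture.conditional_params(0.0, w, mu, cov)
            comp = r1.choice(wc.size, size=n, p=wc)
            exact = r1.normal(mc[comp], np.sqrt(vc[comp]))
            env = _mixture.conditional_envelope(0.0, w, mu, cov, y_range)
            rej = np.array(
                [
                    _mixture.draw_conditional_rejection(0.0, w, mu, cov, r2, y_range, envelope=env)
                    for _ in range(n)
                ]
            )
            passes += stats.ks_2samp(exact, rej).pvalue > 0.01
        assert passes >= 4

    def test_chain_pair_histogram_matches_model_joint(self, fitted_results):
        # non-overlapping consecutive pairs from the chain are marginally
        # distributed as the joint; compare their 2D histogram against a large
        # iid reference sample by total variation (sampling noise at n=20000
        # over ~150 occupied bins is ~0.03; a wrong kernel would exceed 0.1)
        draws = fitted_results.sample_chain(40_000, seed=3, method="exact")
        pairs = np.column_stack([draws[:-1:2], draws[1::2]])
        iid = fitted_results.sample_pairs(n=200_000, seed=4)
        edges = np.linspace(-2.5, 1.5, 23)
        h1, _, _ = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=[edges, edges])
        h2, _, _ = np.histogram2d(iid[:, 0], iid[:, 1], bins=[edges, edges])
        tv = 0.5 * np.abs(h1 / h1.sum() - h2 / h2.sum()).sum()
        assert tv < 0.05


class TestSurrogateTrains:
    def test_event_count_and_burn_in_contract(self, fitted_results):
        rate = BetaRateModel(a=2.0, b=5.0, scale_Hz=12.0)
        train = fitted_results.simulate_train(rate, n_events=500, seed=5)
        assert train.psp_times_s.size == 500
        assert train.n_burn_in == 200

    def test_realized_frequency_tracks_beta_draw(self, fitted_results):
        rate = BetaRateModel(a=2.0, b=5.0, scale_Hz=12.0)
        train = fitted_results.simulate_train(rate, n_events=2000, seed=7)
        assert abs(train.realized_frequency_Hz() / train.target_frequency_Hz - 1.0) < 0.05

    def test_binary_signal_contract(self, fitted_results):
        rate = BetaRateModel(a=2.0, b=5.0, scale_Hz=12.0)
        train = fitted_results.simulate_train(rate, n_events=300, seed=8)
        sig = train.binary_signal
        assert set(np.unique(sig)) <= {0, 1}
        idx = np.floor(train.psp_times_s / train.bin_s).astype(int)
        assert np.all(sig[idx[idx < sig.size]] == 1)

    def test_generation_reproducible_per_seed(self, fitted_results):
        rate = BetaRateModel(a=2.0, b=5.0, scale_Hz=12.0)
        a = fitted_results.simulate_train(rate, n_events=200, seed=9)
        b = fitted_results.simulate_train(rate, n_events=200, seed=9)
        assert np.array_equal(a.psp_times_s, b.psp_times_s)

    def test_binarize_small_instance(self):
        sig = binarize([0.001, 0.015, 0.016], bin_s=0.01, duration_s=0.05)
        np.testing.assert_array_equal(sig, [1, 1, 0, 0, 0])


class TestBetaRateModel:
    def test_known_scale_moment_recovery(self):
        rng = np.random.default_rng(11)
        f = rng.beta(2.0, 5.0, size=2000) * 10.0
        m = BetaRateModel.fit(f, scale_Hz=10.0)
        assert m.a == pytest.approx(2.0, rel=0.1)
        assert m.b == pytest.approx(5.0, rel=0.1)

    def test_default_scale_exceeds_observations(self):
        rng = np.random.default_rng(12)
        f = rng.beta(2.0, 2.0, size=500) * 4.0
        m = BetaRateModel.fit(f)
        assert m.scale_Hz > f.max()
        assert 0 < m.sample(np.random.default_rng(0)) < m.scale_Hz

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            BetaRateModel.fit([1.0])
        with pytest.raises(ValueError):
            BetaRateModel(a=-1.0, b=2.0, scale_Hz=5.0)


class TestPersistence:
    def test_json_round_trip(self, fitted_results, tmp_path):
        path = tmp_path / "model.json"
        fitted_results.to_json(path)
        back = SecondOrderIntervalResults.from_json(path)
        np.testing.assert_allclose(back.means, fitted_results.means)
        np.testing.assert_allclose(back.covariances, fitted_results.covariances)
        assert back.n_components == fitted_results.n_components

    def test_summary_mentions_selection(self, fitted_results):
        text = fitted_results.summary()
        assert "components: 3" in text and "BIC" in text
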