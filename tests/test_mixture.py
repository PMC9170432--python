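"""Histogram construction and the EM mixture fit, checked against
closed forms, hand arithmetic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import histoseg as hs
from histoseg.mixture import (EMConfig, GMMParams, SampleSet, build_histogram,
                              e_step_responsibilities, fit_gmm_em,
                              gaussian_pdf, log_likelihood, m_step_update,
                              mixture_density, q_function, select_components)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------


class TestBuildHistogram:
    def test_constant_image_single_bin(self):
        h = build_histogram(np.full((10, 10), 7.0), n_bins=8)
        assert h.total == 100
        assert (h.counts > 0).sum() == 1
        assert h.counts.max() == 100

    def test_uniform_grid_counts_by_hand(self):
        img = np.arange(9.0).reshape(3, 3)
        h = build_histogram(img, n_bins=3, value_range=(0.0, 9.0))
        np.testing.assert_array_equal(h.counts, [3, 3, 3])

    def test_max_value_lands_in_last_bin(self):
        h = build_histogram(np.array([0.0, 1.0, 2.0]), n_bins=2)
        assert h.counts[-1] >= 1
        assert h.total == 3

    def test_nan_pixels_are_ignored(self):
        img = np.array([1.0, np.nan, 2.0, np.inf, 3.0])
        assert build_histogram(img, n_bins=4).total == 3

    @pytest.mark.parametrize("bad", [np.full(4, np.nan), np.array([])])
    def test_no_finite_values_rejected(self, bad):
        with pytest.raises(ValueError):
            build_histogram(bad, n_bins=4)

    def test_non_increasing_range_rejected(self):
        with pytest.raises(ValueError):
            build_histogram(np.arange(5.0), n_bins=3, value_range=(5.0, 1.0))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
           st.integers(1, 64))
    def test_counts_conserve_pixels(self, values, n_bins):
        img = np.array(values)
        assert build_histogram(img, n_bins=n_bins).total == img.size

    def test_histogram_round_trips_as_weighted_samples(self):
        img = np.repeat([1.0, 2.0, 5.0], [3, 4, 2])
        s = build_histogram(img, n_bins=64).to_sample_set()
        assert s.M == pytest.approx(9)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


class TestGaussianDensity:
    def test_standard_normal_peak(self):
        assert gaussian_pdf(0.0, 0.0, 1.0) == pytest.approx(0.3989422804, abs=1e-9)

    @pytest.mark.parametrize("mu,sigma2", [(3.0, 4.0), (-1.5, 0.25)])
    def test_peak_value_closed_form(self, mu, sigma2):
        assert gaussian_pdf(mu, mu, sigma2) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi * sigma2))

    def test_symmetry_about_mean(self):
        for d in (0.3, 1.7, 5.0):
            assert gaussian_pdf(2.0 + d, 2.0, 3.0) == pytest.approx(
                gaussian_pdf(2.0 - d, 2.0, 3.0))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_pdf(0.0, 0.0, 0.0)


class TestMixtureDensity:
    def test_single_component_equals_gaussian(self):
        p = GMMParams.from_arrays([1.0], [5.0], [2.0])
        x = np.linspace(-5, 15, 11)
        np.testing.assert_allclose(mixture_density(x, p),
                                   gaussian_pdf(x, 5.0, 2.0))

    def test_symmetric_mixture_symmetric_about_center(self):
        p = GMMParams.from_arrays([0.5, 0.5], [-2.0, 2.0], [1.0, 1.0])
        for d in (0.5, 1.0, 3.0):
            assert mixture_density(d, p) == pytest.approx(mixture_density(-d, p))

    def test_integrates_to_one(self):
        p = GMMParams.from_arrays([0.3, 0.7], [0.0, 10.0], [1.0, 4.0])
        x = np.linspace(-30.0, 50.0, 20_001)
        integral = np.trapezoid(mixture_density(x, p), x)
        assert integral == pytest.approx(1.0, abs=1e-3)


# ---------------------------------------------------------------------------
# E-step / M-step against scalar oracles
# ---------------------------------------------------------------------------


def _scalar_responsibilities(values, params):
    """Direct per-term posterior arithmetic, no vectorization."""
    out = np.zeros((len(values), params.L))
    for i, x in enumerate(values):
        dens = [pi * gaussian_pdf(x, mu, s2) for pi, mu, s2 in
                zip(params.pis, params.mus, params.sigma2s)]
        out[i] = np.array(dens) / sum(dens)
    return out


class TestEStep:
    def test_identical_components_give_mixing_weights(self):
        p = GMMParams.from_arrays([0.3, 0.7], [1.0, 1.0], [2.0, 2.0])
        r = e_step_responsibilities(SampleSet.from_values([0.0, 1.0, 5.0]), p)
        np.testing.assert_allclose(r, np.tile([0.3, 0.7], (3, 1)))

    def test_midpoint_of_equal_components_is_even_split(self):
        p = GMMParams.from_arrays([0.5, 0.5], [0.0, 4.0], [1.0, 1.0])
        r = e_step_responsibilities(SampleSet.from_values([2.0]), p)
        np.testing.assert_allclose(r, [[0.5, 0.5]], atol=1e-12)

    @pytest.mark.parametrize("values,pis,mus,sig2s", [
        ([0.0, 1.5, 4.0], [0.2, 0.8], [0.0, 3.0], [1.0, 2.0]),
        ([-1.0, 0.0, 2.0, 7.0, 9.0], [0.5, 0.3, 0.2], [0.0, 5.0, 9.0],
         [1.0, 4.0, 0.5]),
    ])
    def test_matches_scalar_oracle(self, values, pis, mus, sig2s):
        p = GMMParams.from_arrays(pis, mus, sig2s)
        r = e_step_responsibilities(SampleSet.from_values(values), p)
        np.testing.assert_allclose(r, _scalar_responsibilities(values, p),
                                   atol=1e-12)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-9)

    def test_extreme_outlier_never_divides_by_zero(self):
        p = GMMParams.from_arrays([0.5, 0.5], [0.0, 1.0], [0.01, 0.01])
        r = e_step_responsibilities(SampleSet.from_values([1e6]), p)
        assert np.all(np.isfinite(r))
        assert r.sum() == pytest.approx(1.0)


class TestMStep:
    def test_single_component_recovers_weighted_moments(self):
        s = SampleSet.from_values([1.0, 2.0, 3.0, 10.0], [1.0, 2.0, 1.0, 1.0])
        p = m_step_update(s, np.ones((4, 1)))
        mean = np.average(s.values, weights=s.weights)
        var = np.average((s.values - mean) ** 2, weights=s.weights)
        assert p.pis[0] == pytest.approx(1.0)
        assert p.mus[0] == pytest.approx(mean)
        assert p.sigma2s[0] == pytest.approx(var)

    def test_fixed_responsibilities_match_hand_arithmetic(self):
        s = SampleSet.from_values([0.0, 1.0, 2.0, 3.0])
        r = np.array([[1.0, 0.0], [0.8, 0.2], [0.3, 0.7], [0.0, 1.0]])
        p = m_step_update(s, r)
        # hand-weighted averages, denominators are the column sums
        n0, n1 = 2.1, 1.9
        mu0 = (0.8 * 1 + 0.3 * 2) / n0
        mu1 = (0.2 * 1 + 0.7 * 2 + 1.0 * 3) / n1
        assert p.pis[0] == pytest.approx(n0 / 4)
        assert p.mus[0] == pytest.approx(mu0)
        assert p.mus[1] == pytest.approx(mu1)
        var1 = (0.2 * (1 - mu1) ** 2 + 0.7 * (2 - mu1) ** 2
                + 1.0 * (3 - mu1) ** 2) / n1
        assert p.sigma2s[1] == pytest.approx(var1)
        assert p.pis.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_component_is_reseeded_not_crashed(self):
        s = SampleSet.from_values([0.0, 0.1, 0.2, 9.0])
        r = np.column_stack([np.ones(4), np.zeros(4)])
        prev = GMMParams.from_arrays([0.9, 0.1], [0.1, 5.0], [1.0, 1.0])
        p = m_step_update(s, r, prev_params=prev)
        assert p.L == 2
        assert np.all(np.isfinite(p.mus))
        # the reseeded component lands on the least-explained sample
        assert 9.0 in p.mus


class TestLogLikelihoodAndQ:
    def test_single_sample_at_mean_closed_form(self):
        p = GMMParams.from_arrays([1.0], [3.0], [1.0])
        ll = log_likelihood(SampleSet.from_values([3.0]), p)
        assert ll == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)), abs=1e-9)
        assert ll == pytest.approx(-0.9189, abs=1e-4)

    def test_linear_in_weights(self):
        p = GMMParams.from_arrays([0.4, 0.6], [0.0, 5.0], [1.0, 2.0])
        v = np.array([0.3, 4.0, 6.0])
        s1 = SampleSet.from_values(v)
        s2 = SampleSet.from_values(v, np.full(3, 2.0))
        assert log_likelihood(s2, p) == pytest.approx(2 * log_likelihood(s1, p))

    def test_q_single_component_equals_log_likelihood(self):
        p = GMMParams.from_arrays([1.0], [1.0], [2.0])
        s = SampleSet.from_values([0.0, 1.0, 4.0])
        assert q_function(s, p, np.ones((3, 1))) == pytest.approx(
            log_likelihood(s, p))

    def test_q_small_instance_term_by_term(self):
        s = SampleSet.from_values([0.0, 2.0])
        p = GMMParams.from_arrays([0.25, 0.75], [0.0, 2.0], [1.0, 1.0])
        r = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = 0.0
        for i, x in enumerate(s.values):
            for l in range(2):
                expected += r[i, l] * (np.log(p.pis[l])
                                       + np.log(gaussian_pdf(x, p.mus[l],
                                                             p.sigma2s[l])))
        assert q_function(s, p, r) == pytest.approx(expected, abs=1e-12)

    def test_m_step_maximizes_q(self):
        rng = np.random.default_rng(0)
        s = SampleSet.from_values(rng.normal(0, 1, 50))
        p0 = GMMParams.from_arrays([0.5, 0.5], [-1.0, 1.0], [1.0, 1.0])
        r = e_step_responsibilities(s, p0)
        p1 = m_step_update(s, r)
        assert q_function(s, p1, r) >= q_function(s, p0, r) - 1e-10


# ---------------------------------------------------------------------------
# full EM
# ---------------------------------------------------------------------------


class TestFitGMM:
    def test_single_component_one_shot(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10.0, 2.0, 500)
        p, _, trace = fit_gmm_em(x, 1)
        assert p.mus[0] == pytest.approx(x.mean(), abs=1e-9)
        assert p.sigma2s[0] == pytest.approx(x.var(), rel=1e-6)

    def test_parameter_recovery_two_components(self, two_component_draws):
        truth, samples, _ = two_component_draws
        p, _, trace = fit_gmm_em(samples, 2, EMConfig(seed=0))
        assert np.all(np.abs(p.mus - truth.mus) < 2.0)
        assert np.all(np.abs(p.pis - truth.pis) < 0.03)
        assert trace.converged

    def test_log_likelihood_nondecreasing(self, two_component_draws):
        _, samples, _ = two_component_draws
        for init in ("kmeans", "quantile", "random"):
            _, _, trace = fit_gmm_em(samples, 2, EMConfig(seed=3,
                                                          init_method=init))
            diffs = np.diff(trace.log_likelihood_per_iter)
            assert np.all(diffs >= -1e-8)

    def test_canonical_order_and_row_sums(self, two_component_draws):
        _, samples, _ = two_component_draws
        p, r, _ = fit_gmm_em(samples, 2)
        assert np.all(np.diff(p.mus) > 0)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-9)
        assert p.pis.sum() == pytest.approx(1.0, abs=1e-9)

    def test_beats_grid_search_on_constrained_subproblem(self):
        """EM's optimum is at least as good as a dense (mu1, mu2) grid
        with the true weights and variances held fixed."""
        truth = GMMParams.from_arrays([0.5, 0.5], [0.0, 20.0], [4.0, 4.0])
        samples, _ = hs.simulate_gmm_samples(truth, 2000, seed=9)
        p, _, _ = fit_gmm_em(samples, 2, EMConfig(tol=1e-10, max_iter=2000))
        em_ll = log_likelihood(samples, p)
        best = -np.inf
        for m1 in np.linspace(-1.0, 1.0, 41):
            for m2 in np.linspace(19.0, 21.0, 41):
                cand = GMMParams.from_arrays([0.5, 0.5], [m1, m2], [4.0, 4.0])
                best = max(best, log_likelihood(samples, cand))
        assert em_ll >= best - 1e-6

    def test_histogram_fit_approaches_raw_fit(self, two_component_draws):
        _, samples, _ = two_component_draws
        p_raw, _, _ = fit_gmm_em(samples, 2, EMConfig(seed=0))
        hist = build_histogram(samples.values, n_bins=2000)
        p_hist, _, _ = fit_gmm_em(hist, 2, EMConfig(seed=0))
        bin_width = np.diff(hist.bin_edges).max()
        assert np.all(np.abs(p_raw.mus - p_hist.mus) < 2 * bin_width)
        assert np.all(np.abs(p_raw.pis - p_hist.pis) < 0.01)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_gmm_em(np.array([1.0, 1.0, 2.0]), 3)

    def test_weights_duplicate_equivalence(self):
        """Integer weights behave exactly like repeated samples."""
        v = np.array([1.0, 2.0, 8.0, 9.0])
        w = np.array([2.0, 1.0, 1.0, 2.0])
        expanded = np.repeat(v, w.astype(int))
        p_w, _, _ = fit_gmm_em(SampleSet.from_values(v, w), 2, EMConfig(seed=0))
        p_e, _, _ = fit_gmm_em(expanded, 2, EMConfig(seed=0))
        np.testing.assert_allclose(p_w.mus, p_e.mus, atol=1e-6)
        np.testing.assert_allclose(p_w.pis, p_e.pis, atol=1e-6)


class TestSelectComponents:
    def test_two_component_data_selects_two(self):
        truth = GMMParams.from_arrays([0.5, 0.5], [0.0, 30.0], [4.0, 4.0])
        samples, _ = hs.simulate_gmm_samples(truth, 3000, seed=5)
        best, scores = select_components(samples, [1, 2, 3, 4])
        assert best == 2
        assert len(scores) == 4

    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(6)
        best, _ = select_components(rng.normal(0, 1, 3000), [1, 2, 3])
        assert best == 1

    def test_singleton_candidate_returned(self):
        rng = np.random.default_rng(7)
        best, _ = select_components(rng.normal(0, 1, 100), [2])
        assert best == 2

    def test_impossible_candidate_skipped_with_warning(self):
        x = np.repeat([1.0, 2.0], 50)
        with pytest.warns(UserWarning, match="failed to fit"):
            best, _ = select_components(x, [2, 5])
        assert best == 2


class TestHistogramGMMEstimator:
    def test_sklearn_protocol(self, two_component_draws):
        from sklearn.base import clone
        truth, samples, _ = two_component_draws
        est = hs.HistogramGMM(n_components=2, random_state=0)
        clone(est)  # get_params/set_params round-trip
        est.fit(samples.values)
        assert est.means_.shape == (2,)
        assert np.all(np.diff(est.means_) > 0)
        proba = est.predict_proba(np.array([30.0, 120.0]))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert est.predict(np.array([30.0, 120.0])).tolist() == [0, 1]

    def test_weighted_fit_matches_histogram(self, two_component_draws):
        _, samples, _ = two_component_draws
        hist = build_histogram(samples.values, n_bins=256)
        s = hist.to_sample_set()
        est = hs.HistogramGMM(n_components=2, random_state=0).fit(
            s.values, sample_weight=s.weights)
        direct, _, _ = fit_gmm_em(hist, 2, EMConfig(seed=0))
        np.testing.assert_allclose(est.means_, direct.mus)


class TestSerialization:
    def test_gmm_params_json_round_trip(self, tmp_path):
        p = GMMParams.from_arrays([0.3, 0.7], [1.0, 5.0], [0.5, 2.0])
        path = tmp_path / "params.json"
        p.to_json(path)
        q = GMMParams.from_json(path)
        np.testing.assert_allclose(q.mus, p.mus)
        np.testing.assert_allclose(q.pis, p.pis)

    def test_histogram_csv(self, tmp_path):
        h = build_histogram(np.arange(10.0), n_bins=5)
        path = tmp_path / "hist.csv"
        h.to_csv(path)
        import pandas as pd
        table = pd.read_csv(path)
        assert list(table.columns) == ["bin_center", "count"]
        assert table["count"].sum() == 10
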