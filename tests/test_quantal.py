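"""CV analysis, histogram construction, mixed-Gaussian global fits, K-S."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gluquant import (CvAnalysis, GroundTruth, QuantalHistogramModel,
                      StimulusProtocol, binomial_weights, build_histograms,
                      classify_model, cv_global_fit, cv_slope,
                      fit_binomial_global, fit_poisson_global,
                      fit_pooled_gaussian_mixture, ks_goodness,
                      poisson_weights, select_best_n, select_min_n,
                      simulate_peak_table, usable_roi_fraction)
from gluquant.quantal import QuantalFit


def enumerate_site_outcomes(n_sites: int, p: float) -> np.ndarray:
    """Oracle PMF by explicit enumeration of all 2^N site outcomes."""
    pmf = np.zeros(n_sites + 1)
    for outcome in itertools.product([0, 1], repeat=n_sites):
        k = sum(outcome)
        pmf[k] += np.prod([p if o else 1 - p for o in outcome])
    return pmf


def _peak_table(amp_by_roi_train: dict) -> pd.DataFrame:
    """Build a minimal peak table: roi -> list of per-train amplitude lists."""
    rows = []
    for roi, trains in amp_by_roi_train.items():
        for t, amps in enumerate(trains):
            for si, a in enumerate(amps):
                rows.append((roi, "2", t, si, a, a == 0, 10.0, False, ""))
    return pd.DataFrame(rows, columns=[
        "roi_id", "condition", "train", "stimulus_index", "amplitude",
        "is_failure", "snr", "excluded", "reason"])


class TestBinomialOracle:
    @pytest.mark.parametrize("n_sites", range(1, 7))
    @pytest.mark.parametrize("p", [0.1, 0.4, 0.9])
    def test_weights_equal_enumerated_site_outcomes(self, n_sites, p):
        expected = enumerate_site_outcomes(n_sites, p)
        np.testing.assert_allclose(binomial_weights(n_sites, p), expected,
                                   atol=1e-12)

    def test_weights_sum_to_one(self):
        assert binomial_weights(8, 0.37).sum() == pytest.approx(1.0)

    def test_poisson_truncation_keeps_required_mass(self):
        w = poisson_weights(2.0)
        assert w.sum() > 0.999


class TestCvRoute:
    def test_proportional_points_give_exact_slope(self):
        """Per-ROI SD exactly 0.5 x mean -> CV 0.5 with R^2 = 1."""
        table = {}
        for i, m in enumerate((0.2, 0.4, 0.6, 0.8)):
            d = 0.5 * m / np.sqrt(2.0)  # sd of [m+d, m-d] is d*sqrt(2)
            table[f"r{i}"] = [[m + d, m - d], [m + d, m - d]]
        cv, r2, pts = cv_slope(_peak_table(table), "2")
        assert cv == pytest.approx(0.5, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sd_gives_zero_cv(self):
        table = {f"r{i}": [[0.3, 0.3], [0.3, 0.3]] for i in range(4)}
        cv, r2, _ = cv_slope(_peak_table(table), "2")
        assert cv == 0.0

    def test_too_few_rois_rejected(self):
        table = {"r0": [[0.1, 0.2], [0.2, 0.1]]}
        with pytest.raises(ValueError, match="ROIs"):
            cv_slope(_peak_table(table), "2")

    def test_binomial_cv_closed_form_recovered(self):
        """Simulated (N=5, P=0.4) ROIs: CV near sqrt(0.3) ~ 0.548."""
        gt = GroundTruth(noise_sd=0.005, seed=21)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=100,
                                    seed=21)
        cv, _, _ = cv_slope(table, "2")
        assert cv == pytest.approx(np.sqrt(0.3), rel=0.10)

    def test_inversion_is_exact(self):
        fits = cv_global_fit({"2": 0.0}, (1, 4))
        assert np.allclose(fits["p_release_2"], 1.0)
        fits = cv_global_fit({"2": 1.0}, (1, 1))
        assert fits["p_release_2"].iloc[0] == pytest.approx(0.5)
        fits = cv_global_fit({"2": np.sqrt(0.3)}, (5, 5))
        assert fits["p_release_2"].iloc[0] == pytest.approx(0.4, abs=1e-12)

    def test_select_min_n_patterns(self):
        fits = pd.DataFrame({
            "n_sites": [1, 2, 3, 4],
            "p_release_0.5": [0.8, 0.6, 0.45, 0.3]})
        assert select_min_n(fits, "0.5") == 3
        fits_low = pd.DataFrame({"n_sites": [1],
                                 "p_release_0.5": [0.4]})
        assert select_min_n(fits_low, "0.5") == 1
        fits_high = pd.DataFrame({"n_sites": [1, 2],
                                  "p_release_0.5": [0.9, 0.8]})
        assert select_min_n(fits_high, "0.5") is None

    def test_cv_analysis_estimator_on_study_data(self):
        gt = GroundTruth(noise_sd=0.01, seed=8)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=60,
                                    seed=8)
        cv = CvAnalysis().fit(table)
        assert cv.n_sites_ is not None
        ps = [cv.p_release_[c] for c in ("0.5", "2", "4")]
        assert ps[0] < ps[1] < ps[2]


class TestHistograms:
    def test_counts_conserved_across_binning(self):
        amps = {"0.5": np.zeros(50), "2": np.full(50, 0.1),
                "4": np.full(50, 0.3)}
        counts, pooled, edges = build_histograms(amps, 0.03)
        assert pooled.sum() == 150
        assert sum(c.sum() for c in counts.values()) == 150

    def test_failures_land_in_first_bin(self):
        counts, pooled, edges = build_histograms({"2": np.zeros(30)}, 0.05)
        assert counts["2"][0] == 30
        assert counts["2"][1:].sum() == 0

    def test_binning_arithmetic(self):
        counts, pooled, edges = build_histograms(
            {"2": np.array([0.0, 0.09, 0.18])}, 0.05)
        occupied = np.nonzero(counts["2"])[0]
        np.testing.assert_array_equal(occupied, [0, 1, 3])

    def test_no_responses_rejected(self):
        with pytest.raises(ValueError):
            build_histograms({"2": np.array([])}, 0.05)


class TestPooledQuantalSize:
    def test_spacing_recovered_within_fifteen_percent(self):
        gt = GroundTruth(seed=13)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=1, seed=13)
        q_hat, diag = fit_pooled_gaussian_mixture(table["amplitude"].to_numpy())
        assert not diag["fallback"]
        assert q_hat == pytest.approx(0.09, rel=0.15)

    def test_scale_equivariance(self):
        gt = GroundTruth(seed=13)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=1, seed=13)
        amps = table["amplitude"].to_numpy()
        q1, _ = fit_pooled_gaussian_mixture(amps)
        q2, _ = fit_pooled_gaussian_mixture(2 * amps, bin_width=0.02)
        assert q2 == pytest.approx(2 * q1, rel=0.10)

    def test_single_mode_falls_back(self):
        rng = np.random.default_rng(0)
        amps = rng.normal(0.09, 0.01, 200).clip(0.01)
        q_hat, diag = fit_pooled_gaussian_mixture(amps)
        assert diag["fallback"]
        assert q_hat == pytest.approx(np.median(amps), rel=0.05)


class TestGlobalFits:
    def test_binomial_recovery_n7(self):
        """(N=7, q=0.09, P=0.1/0.4/0.7), noise-free: q and P recovered."""
        gt = GroundTruth(n_sites=7, noise_sd=0.0, seed=31)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=1, seed=31)
        amps = table["amplitude"].to_numpy()
        conds = table["condition"].astype(str).to_numpy()
        by = {c: amps[conds == c] for c in ("0.5", "2", "4")}
        fit = fit_binomial_global(by, 7, init_q=0.09, seed=1)
        assert fit.converged
        assert fit.q == pytest.approx(0.09, rel=0.05)
        for c, p in gt.p_release.items():
            assert fit.p_release[c] == pytest.approx(p, abs=0.05)

    def test_mixture_weights_normalised_at_optimum(self):
        w = binomial_weights(7, 0.42)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_saturated_release_concentrates_in_one_peak(self):
        rng = np.random.default_rng(2)
        amps = rng.normal(0.09, 0.01, 150).clip(0)
        fit = fit_binomial_global({"2": amps}, 1, init_q=0.09, seed=1)
        assert fit.p_release["2"] > 0.9
        assert fit.q == pytest.approx(0.09, rel=0.1)

    def test_poisson_recovery_lambda2(self):
        """Poisson lambda=2 data: rate and spacing within 10%."""
        gt = GroundTruth(p_release={"2": 0.4}, noise_sd=0.0,
                         quantal_cv=0.3, seed=17)
        proto = StimulusProtocol(conditions=("2",), trains_per_condition=30)
        table = simulate_peak_table(gt, proto, n_rois=1, model="poisson",
                                    seed=17)
        amps = table["amplitude"].to_numpy()
        fit = fit_poisson_global({"2": amps}, init_q=0.09, seed=1)
        assert fit.lambda_rate["2"] == pytest.approx(2.0, rel=0.10)
        assert fit.q == pytest.approx(0.09, rel=0.10)

    def test_vanishing_rate_fills_failure_bin(self):
        """lambda -> 0: the model puts all predicted mass at amplitude 0."""
        from gluquant.quantal import _predicted_counts
        edges = np.arange(0.0, 0.5, 0.03)
        pred = _predicted_counts(edges, "poisson", None, 1e-6, 0.09, 0.02,
                                 150.0)
        assert pred[0] == pytest.approx(150.0, rel=1e-4)
        assert pred[1:].sum() < 1e-3


class TestKsGoodness:
    def _fit(self):
        return QuantalFit(model="binomial", q=0.09, sigma_component=0.02,
                          scale=150.0, n_sites=5,
                          p_release={"2": 0.4})

    def _sample(self, n, rng, shift=0.0):
        fit = self._fit()
        w = binomial_weights(5, 0.4)
        ks = rng.choice(6, size=n, p=w)
        amps = np.where(ks == 0, 0.0,
                        rng.normal(ks * 0.09 + shift, 0.02)).clip(0)
        amps[ks == 0] = 0.0
        return amps

    def test_model_samples_fit_well(self, rng):
        amps = self._sample(4000, rng)
        d, p = ks_goodness(amps, self._fit(), "2")
        assert d < 0.03
        assert 0 <= d <= 1

    def test_shifted_sample_strongly_rejected(self, rng):
        amps = self._sample(150, rng, shift=0.09)
        d, p = ks_goodness(amps, self._fit(), "2")
        assert p < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_goodness(np.array([]), self._fit(), "2")


class TestModelSelection:
    def test_singleton_range_returns_that_n(self):
        gt = GroundTruth(seed=5)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=1, seed=5)
        amps = table["amplitude"].to_numpy()
        conds = table["condition"].astype(str).to_numpy()
        by = {c: amps[conds == c] for c in ("0.5", "2", "4")}
        fit, per_n = select_best_n(by, (6, 6), init_q=0.09, seed=1)
        assert fit.n_sites == 6

    def test_plateau_prefers_smallest_adequate_n(self):
        """True N=5 selected from the brute-force scan (study conditions)."""
        gt = GroundTruth(seed=12)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=1, seed=12)
        amps = table["amplitude"].to_numpy()
        conds = table["condition"].astype(str).to_numpy()
        by = {c: amps[conds == c] for c in ("0.5", "2", "4")}
        fit, per_n = select_best_n(by, (1, 12), seed=1)
        assert fit.n_sites == 5
        skipped = per_n[per_n["skipped"]]
        assert (skipped["n_sites"] < 5).all()  # too-small N never fitted

    def test_classification_flags(self):
        fit = QuantalFit(model="binomial", q=0.09, sigma_component=0.02,
                         scale=1.0, n_sites=5, ks_p={"2": 0.5})
        other = QuantalFit(model="poisson", q=0.09, sigma_component=0.02,
                           scale=1.0, n_sites=None, ks_p={"2": 0.5})
        res = classify_model(fit, other)
        assert res["preferred"] == "tie"
        res = classify_model(fit, None)
        assert res["preferred"] == "binomial"
        assert "unavailable" in res["flag"]
        with pytest.raises(ValueError):
            classify_model(None, None)

    def test_usable_fraction_counts_exclusions_and_convergence(self):
        table = _peak_table({"r0": [[0.1, 0.1]], "r1": [[0.1, 0.1]]})
        good = QuantalFit(model="binomial", q=0.09, sigma_component=0.02,
                          scale=1.0, n_sites=5, converged=True)
        assert usable_roi_fraction(table, {"r0": good, "r1": good}) == 1.0
        assert usable_roi_fraction(table, {"r0": good, "r1": None}) == 0.5
        assert usable_roi_fraction(table, {}) == 0.0
        table.loc[table["roi_id"] == "r1", "excluded"] = True
        assert usable_roi_fraction(table, {"r0": good, "r1": good}) == 0.5


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip_and_fit(self):
        gt = GroundTruth(seed=2)
        table = simulate_peak_table(gt, StimulusProtocol(), n_rois=1, seed=2)
        model = QuantalHistogramModel(n_range=(1, 10), seed=1)
        assert model.get_params()["n_range"] == (1, 10)
        model.set_params(restarts=3)
        model.fit(table["amplitude"].to_numpy(),
                  table["condition"].astype(str).to_numpy())
        assert model.q_ > 0
        assert set(model.p_release_) == {"0.5", "2", "4"}
        assert model.per_n_ is not None
        x = np.linspace(0, 0.6, 50)
        cdf = model.cdf(x, "2")
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[-1] == pytest.approx(1.0, abs=0.01)

    def test_monotone_true_p_increases_fitted_p(self):
        """Raising true P_R raises the fitted P_R (three-level probe)."""
        fitted = []
        for p in (0.2, 0.45, 0.7):
            gt = GroundTruth(p_release={"0.5": 0.1, "2": p, "4": 0.7},
                             seed=33)
            table = simulate_peak_table(gt, StimulusProtocol(), n_rois=1,
                                        seed=33)
            m = QuantalHistogramModel(n_sites=5, seed=1)
            m.fit(table["amplitude"].to_numpy(),
                  table["condition"].astype(str).to_numpy())
            fitted.append(m.p_release_["2"])
        assert fitted[0] < fitted[1] < fitted[2]


def test_cv_and_histogram_routes_agree_on_rank_order():
    """Both routes order P_R monotonically in calcium on shared data."""
    from gluquant.experiments import cv_consistency_experiment
    res = cv_consistency_experiment(n_rois=24, seed=3)
    assert res["cv_monotone"]
    assert res["hist_monotone"]
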