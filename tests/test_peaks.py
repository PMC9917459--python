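"""ALS baseline, peak finding, template extraction and synaptic metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gluquant import (GroundTruth, StimulusProtocol, als_baseline,
                      correct_minis, curate_peaks, depression_ratio,
                      extract_peaks_at_template, find_peaks_wavelet,
                      gaussian_profile_width, neighbour_correlation,
                      rundown_ratio, simulate_trace, snr_and_exclusion)
from gluquant.peaks import AlsBaseline, depression_per_cell, robust_noise_sd
from gluquant.traces import TraceSet


def _traceset(dff, proto):
    dff = np.atleast_2d(dff)
    return TraceSet(dff=dff, f0=np.ones(dff.shape[0]),
                    roi_ids=[f"r{i}" for i in range(dff.shape[0])],
                    frame_rate_hz=proto.frame_rate_hz,
                    stim_table=proto.stim_table())


class TestAlsBaseline:
    def test_constant_trace_is_its_own_baseline(self):
        y = np.full(200, 3.5)
        np.testing.assert_allclose(als_baseline(y), y, atol=1e-9)

    def test_pure_drift_recovered_below_one_percent(self):
        """Peak-free linear drift: baseline RMSE < 1% of the drift range."""
        t = np.arange(600) / 25.0
        drift = 0.03 * t
        z = als_baseline(drift)
        rmse = np.sqrt(np.mean((z - drift) ** 2))
        assert rmse < 0.01 * (drift.max() - drift.min())

    def test_baseline_ignores_positive_transients(self):
        """Drift is tracked, planted transients are not absorbed."""
        rng = np.random.default_rng(2)
        t = np.arange(1000) / 25.0
        drift = 0.1 * (1 - np.exp(-t / 10.0))
        y = drift + rng.normal(0, 0.005, t.size)
        peaks = np.arange(60, 1000, 40)
        for p in peaks:
            y[p:p + 8] += 0.2 * np.exp(-np.arange(8) / 10.0)
        z = als_baseline(y)
        quiet = np.ones(t.size, dtype=bool)
        for p in peaks:
            quiet[p - 1:p + 12] = False
        assert np.abs((z - drift)[quiet]).mean() < 0.01
        corrected = y - z
        assert abs(np.median(corrected)) < 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            als_baseline(np.zeros(5))
        with pytest.raises(ValueError):
            als_baseline(np.zeros(50), asymmetry=1.5)

    def test_transformer_interface(self):
        X = np.vstack([np.linspace(0, 1, 100), np.full(100, 2.0)])
        est = AlsBaseline()
        out = est.fit_transform(X)
        assert out.shape == X.shape
        assert est.baselines_.shape == X.shape
        np.testing.assert_allclose(out[1], 0.0, atol=1e-9)


class TestWaveletPeaks:
    def test_single_planted_transient_found(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.01, 500)
        y[250:258] += 0.1 * np.exp(-np.arange(8) / 5.0)
        idx = find_peaks_wavelet(y)
        assert len(idx) == 1
        assert abs(idx[0] - 250) <= 1

    def test_null_false_positive_rate_below_five_percent(self):
        """On pure noise, detections stay under 5% of 50 nominal stimuli."""
        rng = np.random.default_rng(1)
        n_fp, n_stimuli = 0, 0
        for _ in range(10):
            y = rng.normal(0, 0.02, 750)
            n_fp += len(find_peaks_wavelet(y, min_snr=3.0))
            n_stimuli += 50
        assert n_fp / n_stimuli < 0.05

    def test_resolves_five_frame_separation(self):
        y = np.zeros(300)
        for p in (150, 155):
            y[p:p + 4] += [0.2, 0.18, 0.16, 0.14]
        idx = find_peaks_wavelet(y, width_range=np.arange(1, 5))
        hits = [i for i in idx if 148 <= i <= 158]
        assert len(hits) == 2

    def test_empty_trace_gives_empty_result(self):
        assert find_peaks_wavelet(np.array([])).size == 0

    def test_curation_hook_adds_and_removes(self):
        idx = np.array([10, 20, 30])
        out = curate_peaks(idx, add=[40], remove=[20])
        np.testing.assert_array_equal(out, [10, 30, 40])


class TestTemplateExtraction:
    def test_noise_free_counts_recovered_exactly(self):
        """counts (2,0,1) with q=0.09 -> amplitudes (0.18, 0, 0.09)."""
        gt = GroundTruth(noise_sd=0.0, drift_amplitude=0.0, seed=0)
        proto = StimulusProtocol(conditions=("2",), trains_per_condition=1,
                                 stimuli_per_train=3)
        dff = simulate_trace({"2": np.array([2, 0, 1])}, gt, proto)
        ts = _traceset(dff, proto)
        table = extract_peaks_at_template(
            ts, template_indices=proto.stimulus_frames(), decay_tau_s=0.4,
            corrected=np.atleast_2d(dff))
        np.testing.assert_allclose(table["amplitude"], [0.18, 0.0, 0.09],
                                   atol=1e-12)
        assert list(table["is_failure"]) == [False, True, False]

    def test_roi_equal_to_mean_waveform_returns_own_peaks(self):
        gt = GroundTruth(noise_sd=0.0, drift_amplitude=0.0, seed=0)
        proto = StimulusProtocol(conditions=("2",), trains_per_condition=2)
        counts = {"2": np.tile([3, 1, 2, 1, 4], 2)}
        dff = simulate_trace(counts, gt, proto)
        ts = _traceset(np.vstack([dff, dff]), proto)
        table = extract_peaks_at_template(ts, decay_tau_s=0.4,
                                          corrected=np.vstack([dff, dff]))
        a = table[table["roi_id"] == "r0"]["amplitude"].to_numpy()
        b = table[table["roi_id"] == "r1"]["amplitude"].to_numpy()
        np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(a, np.tile([3, 1, 2, 1, 4], 2) * 0.09,
                                   atol=1e-6)

    def test_failures_pinned_to_exact_zero_under_noise(self):
        gt = GroundTruth(noise_sd=0.02, drift_amplitude=0.0, seed=5)
        proto = StimulusProtocol(conditions=("2",), trains_per_condition=2)
        counts = {"2": np.tile([3, 0, 2, 0, 4], 2)}
        rng = np.random.default_rng(5)
        dff = simulate_trace(counts, gt, proto, rng=rng)
        ts = _traceset(dff, proto)
        table = extract_peaks_at_template(
            ts, template_indices=proto.stimulus_frames(), decay_tau_s=0.4)
        failures = table.loc[table["is_failure"], "amplitude"]
        assert len(failures) >= 2
        assert np.all(failures == 0.0)

    def test_invalid_f0_roi_excluded(self):
        proto = StimulusProtocol(conditions=("2",), trains_per_condition=1)
        dff = np.full((1, proto.n_frames_total), np.nan)
        ts = _traceset(dff, proto)
        ts.valid[0] = False
        table = extract_peaks_at_template(
            ts, template_indices=proto.stimulus_frames(), decay_tau_s=0.4,
            corrected=dff)
        assert table["excluded"].all()
        assert (table["reason"] == "invalid F0").all()

    def test_empty_template_rejected(self):
        proto = StimulusProtocol(conditions=("2",), trains_per_condition=1)
        dff = np.zeros((1, proto.n_frames_total))
        ts = _traceset(dff, proto)
        ts.stim_table = ts.stim_table.iloc[0:0]
        with pytest.raises(ValueError, match="template"):
            extract_peaks_at_template(ts, template_indices=np.array([]),
                                      corrected=dff, decay_tau_s=0.4)


class TestRundownAndDepression:
    def test_constant_amplitudes_give_unity(self):
        assert rundown_ratio(np.full(50, 0.2)) == pytest.approx(1.0)

    def test_last_half_of_first_is_boundary(self):
        a = np.full(50, 1.0)
        a[-5:] = 0.5
        assert rundown_ratio(a) == pytest.approx(0.5)

    def test_geometric_decay_closed_form(self):
        """0.97 decay per response over 50: ratio ~ 0.97^45 ~ 0.25."""
        a = 0.97 ** np.arange(50)
        expected = a[-5:].mean() / a[:5].mean()
        assert rundown_ratio(a) == pytest.approx(expected)
        assert expected == pytest.approx(0.97**45, rel=0.01)

    def test_too_few_responses_rejected(self):
        with pytest.raises(ValueError):
            rundown_ratio(np.ones(9))

    def test_zero_first_decile_undefined(self):
        a = np.ones(50)
        a[:5] = 0.0
        assert np.isnan(rundown_ratio(a))

    @pytest.mark.parametrize("train,expected", [
        ((1.0, 0.9, 0.8, 0.7, 0.6), 0.6),
        ((0.3, 0.3, 0.3, 0.3, 0.3), 1.0),
        ((0.5, 0.6, 0.7, 0.9, 1.0), 2.0),
    ])
    def test_depression_ratio_examples(self, train, expected):
        assert depression_ratio(np.array(train)) == pytest.approx(expected)

    def test_zero_first_amplitude_warns_and_is_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(depression_ratio(np.array([0.0, 1.0])))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_ratios_are_scale_invariant(self, scale):
        rng = np.random.default_rng(7)
        amps = rng.uniform(0.1, 1.0, 50)
        assert rundown_ratio(amps * scale) == pytest.approx(
            rundown_ratio(amps), rel=1e-9)
        assert depression_ratio(amps[:5] * scale) == pytest.approx(
            depression_ratio(amps[:5]), rel=1e-9)

    def test_per_cell_mean_over_trains(self):
        rows = []
        for train, amps in enumerate([(1.0, 0.8), (1.0, 0.6)]):
            for si, a in enumerate(amps):
                rows.append(("r0", "2", train, si, a, False, 10.0, False, ""))
        table = pd.DataFrame(rows, columns=[
            "roi_id", "condition", "train", "stimulus_index", "amplitude",
            "is_failure", "snr", "excluded", "reason"])
        assert depression_per_cell(table) == pytest.approx(0.7)


class TestExclusion:
    def _table(self, snr, amps):
        rows = []
        for i, a in enumerate(amps):
            rows.append(("r0", "2", i // 5, i % 5, a, a == 0, snr, False, ""))
        return pd.DataFrame(rows, columns=[
            "roi_id", "condition", "train", "stimulus_index", "amplitude",
            "is_failure", "snr", "excluded", "reason"])

    def test_high_snr_stable_roi_retained(self):
        out = snr_and_exclusion(self._table(8.0, np.full(50, 0.2)))
        assert not out["excluded"].any()

    def test_rundown_roi_excluded_with_reason(self):
        amps = np.full(50, 1.0)
        amps[-5:] = 0.2
        out = snr_and_exclusion(self._table(8.0, amps), rundown_cut=0.5)
        assert out["excluded"].all()
        assert (out["reason"] == "rundown").all()

    def test_boundary_rundown_ratio_not_classified(self):
        amps = np.full(50, 1.0)
        amps[-5:] = 0.5  # ratio exactly 0.5: strict < keeps the ROI
        out = snr_and_exclusion(self._table(8.0, amps), rundown_cut=0.5)
        assert not out["excluded"].any()

    def test_snr_just_below_threshold_excluded(self):
        out = snr_and_exclusion(self._table(2.9, np.full(50, 0.2)),
                                min_snr=3.0)
        assert out["excluded"].all()
        assert (out["reason"] == "low SNR").all()

    def test_exclusion_monotone_in_thresholds(self):
        amps = np.full(50, 1.0)
        amps[-5:] = 0.6
        for lo, hi in [(2.0, 4.0), (0.3, 0.7)]:
            loose = snr_and_exclusion(self._table(3.5, amps),
                                      min_snr=lo if hi == 4.0 else 3.0,
                                      rundown_cut=0.4 if hi == 4.0 else lo)
            strict = snr_and_exclusion(self._table(3.5, amps),
                                       min_snr=hi if hi == 4.0 else 3.0,
                                       rundown_cut=0.4 if hi == 4.0 else hi)
            assert loose["excluded"].sum() <= strict["excluded"].sum()


class TestCorrelationAndProfiles:
    def test_identical_traces_correlate_perfectly(self, rng):
        y = rng.normal(0, 1, 200)
        assert neighbour_correlation(y, y) == pytest.approx(1.0)
        assert neighbour_correlation(y, -y) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(0, 1, 1000)
        assert abs(neighbour_correlation(a, b)) < 0.1

    def test_zero_variance_reported_absent(self):
        assert np.isnan(neighbour_correlation(np.ones(10), np.arange(10.0)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            neighbour_correlation(np.ones(5), np.ones(6))

    def test_gaussian_fwhm_recovered_within_one_percent(self):
        """sigma = 0.191 um corresponds to FWHM 0.45 um."""
        x = np.linspace(-1, 1, 81)
        y = 2.0 * np.exp(-(x**2) / (2 * 0.191**2)) + 0.3
        fit = gaussian_profile_width(x, y)
        assert fit["fwhm_um"] == pytest.approx(0.45, rel=0.01)
        assert fit["sigma_um"] == pytest.approx(0.191, rel=0.01)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            gaussian_profile_width(np.linspace(0, 1, 20), np.ones(20))

    def test_sampled_spot_profile_within_five_percent(self):
        x = np.arange(-2, 2.05, 0.1)
        rng = np.random.default_rng(4)
        y = np.exp(-(x**2) / (2 * 0.3**2)) + rng.normal(0, 0.01, x.size)
        fit = gaussian_profile_width(x, y)
        assert fit["sigma_um"] == pytest.approx(0.3, rel=0.05)


class TestMiniCorrection:
    def test_frequency_difference(self):
        res = correct_minis(2.0, 0.5, 30.0, 10.0)
        assert res.status == "ok"
        assert res.frequency_hz == pytest.approx(1.5)

    def test_small_frequency_difference_discarded(self):
        res = correct_minis(1.00, 0.95, 30.0, 10.0)
        assert res.status == "discarded"
        assert "0.1 Hz" in res.reason

    def test_clean_condition_keeps_control_amplitude(self):
        res = correct_minis(2.0, 0.0, 25.0, 0.0)
        assert res.status == "ok"
        assert res.amplitude_pa == pytest.approx(25.0)

    def test_higher_nbqx_frequency_discarded(self):
        assert correct_minis(1.0, 1.5, 30.0, 10.0).status == "discarded"

    def test_nbqx_amplitude_not_smaller_discarded(self):
        assert correct_minis(2.0, 0.5, 20.0, 25.0).status == "discarded"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            correct_minis(-1.0, 0.5, 30.0, 10.0)

    def test_weighted_amplitude_formula(self):
        res = correct_minis(2.0, 1.0, 30.0, 10.0)
        assert res.amplitude_pa == pytest.approx(
            (2.0 * 30.0 - 1.0 * 10.0) / 1.0)


def test_robust_noise_matches_gaussian_sd(rng):
    y = rng.normal(0, 0.03, 20000)
    assert robust_noise_sd(y) == pytest.approx(0.03, rel=0.05)
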