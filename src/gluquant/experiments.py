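"""Benchmark experiments on synthetic data with known ground truth.

These are the package's standard self-validation studies: quantal-parameter
recovery, release-model classification, planted-spot ROI detection,
baseline/extraction bias, and pipeline determinism. Each function generates
its own data through :mod:`gluquant.synthetic`, runs the production
analysis path, and returns summary statistics.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np

from .peaks import AlsBaseline, extract_peaks_at_template
from .pipeline import RunConfig, run_pipeline
from .quantal import QuantalHistogramModel, classify_model
from .roi import TileRoiDetector, match_rois_to_spots
from .synthetic import (GroundTruth, StimulusProtocol, simulate_movie,
                        simulate_peak_table, simulate_release_counts,
                        simulate_trace)
from .traces import TraceSet

STUDY_P_RELEASE = {"0.5": 0.1, "2": 0.4, "4": 0.7}


def recovery_experiment(
    n_replicates: int = 20,
    n_rois: int = 60,
    seed: int = 1,
    gt_kwargs: dict | None = None,
) -> dict:
    """Quantal-parameter recovery under the study conditions.

    Each replicate simulates ``n_rois`` ROIs with N = 5 sites, q = 0.09,
    P_R = 0.1/0.4/0.7 across calcium conditions and amplitude noise 0.03
    (150 stimuli per ROI), runs the per-ROI brute-force binomial fit, and
    summarises the recovered quantal size, release probabilities, selected
    site counts and the monotonicity of release probability in calcium.
    """
    gt_kwargs = gt_kwargs or {}
    proto = StimulusProtocol()
    selected_n: list[int] = []
    q_rel_err: list[float] = []
    p_abs_err: dict[str, list[float]] = {c: [] for c in STUDY_P_RELEASE}
    monotone = 0
    for rep in range(n_replicates):
        rep_seed = seed * 10_000 + rep
        gt = GroundTruth(seed=rep_seed, **gt_kwargs)
        table = simulate_peak_table(gt, proto, n_rois=n_rois, seed=rep_seed)
        qs, ps = [], {c: [] for c in STUDY_P_RELEASE}
        for _, grp in table.groupby("roi_id", sort=False):
            model = QuantalHistogramModel(model="binomial", seed=seed)
            model.fit(grp["amplitude"].to_numpy(),
                      grp["condition"].astype(str).to_numpy())
            selected_n.append(int(model.n_sites_))
            qs.append(model.q_)
            for c in STUDY_P_RELEASE:
                ps[c].append(model.p_release_[c])
        q_rel_err.append(abs(np.median(qs) - gt.q_true) / gt.q_true)
        med_p = {c: float(np.median(ps[c])) for c in STUDY_P_RELEASE}
        for c, true_p in gt.p_release.items():
            p_abs_err[c].append(abs(med_p[c] - true_p))
        ordered = [med_p[c] for c in ("0.5", "2", "4")]
        monotone += int(ordered[0] < ordered[1] < ordered[2])
    modal_n = Counter(selected_n).most_common(1)[0][0]
    return {
        "median_q_rel_err": float(np.median(q_rel_err)),
        "median_p_abs_err": {c: float(np.median(v))
                             for c, v in p_abs_err.items()},
        "modal_n": int(modal_n),
        "n_counts": dict(Counter(selected_n)),
        "monotone_replicates": int(monotone),
        "n_replicates": n_replicates,
        "n_rois": n_rois,
    }


def classification_experiment(
    n_replicates: int = 50,
    seed: int = 1,
) -> dict:
    """Release-model recovery: binomial vs Poisson preference.

    Each arm generates 150 events (50 per calcium condition) from its own
    observation model -- the binomial arm with fixed quantal amplitude and
    additive noise (constant component widths), the Poisson arm with
    per-vesicle quantal variability and no additive noise (component
    widths growing as sqrt(k)) -- then fits both models and classifies by
    the larger minimum per-condition K-S probability.
    """
    proto = StimulusProtocol()
    correct = {"binomial": 0, "poisson": 0}
    for rep in range(n_replicates):
        for arm in ("binomial", "poisson"):
            rep_seed = seed * 20_000 + rep * 2 + (arm == "poisson")
            if arm == "poisson":
                gt = GroundTruth(noise_sd=0.0, quantal_cv=0.33, seed=rep_seed)
            else:
                gt = GroundTruth(seed=rep_seed)
            table = simulate_peak_table(gt, proto, n_rois=1, model=arm,
                                        seed=rep_seed)
            amps = table["amplitude"].to_numpy()
            conds = table["condition"].astype(str).to_numpy()
            binom = QuantalHistogramModel(model="binomial", seed=seed)
            binom.fit(amps, conds)
            poisson = QuantalHistogramModel(model="poisson", seed=seed)
            poisson.fit(amps, conds)
            choice = classify_model(binom.fit_, poisson.fit_)
            correct[arm] += int(choice["preferred"] == arm)
    return {
        "binomial_correct": correct["binomial"],
        "poisson_correct": correct["poisson"],
        "n_replicates": n_replicates,
    }


def detection_experiment(
    shape: tuple[int, int] = (256, 256),
    n_narrow: int = 10,
    n_broad: int = 10,
    seed: int = 1,
) -> dict:
    """Planted-spot ROI detection on a full-field synthetic movie.

    Narrow (0.3 um) and broad (1.5 um) Gaussian spots respond to 50
    stimuli at tile-level SNR >= 5 with well over 20 qualifying transients
    each; the tile detector's recall, precision and composite areas are
    scored against the planted centres. The default protocol gives a
    1500-frame movie at 25 Hz.
    """
    proto = StimulusProtocol(conditions=("2",), inter_train_s=5.0)
    rng = np.random.default_rng(seed)
    n_spots = n_narrow + n_broad
    H, W = shape
    # jittered grid placement, spots kept well apart so composites stay
    # separable (diffuse spots reach ~ +/-6 px)
    cols = int(np.ceil(np.sqrt(n_spots)))
    pitch_r = (H - 48) // cols
    pitch_c = (W - 48) // int(np.ceil(n_spots / cols))
    centres = []
    for i in range(n_spots):
        r = 24 + (i % cols) * pitch_r + rng.uniform(-6, 6)
        c = 24 + (i // cols) * pitch_c + rng.uniform(-6, 6)
        centres.append((float(r), float(c)))
    traces, gts, peaks = [], [], []
    for i in range(n_spots):
        narrow = i < n_narrow
        gt = GroundTruth(p_release={"2": 0.5}, noise_sd=0.03,
                         spot_sigma_um=0.3 if narrow else 1.5,
                         seed=seed * 30_000 + i)
        sub = np.random.default_rng([seed, i])
        counts = simulate_release_counts(gt, proto, rng=sub)
        traces.append(simulate_trace(counts, gt, proto, rng=sub))
        gts.append(gt)
        peaks.append(4000.0 if narrow else 1200.0)
    movie = simulate_movie(np.stack(traces), centres, gts, proto,
                           shape=shape, background=100.0,
                           pixel_size_um=0.5, spot_peak_counts=peaks)
    detector = TileRoiDetector().fit(movie)
    recall, precision = match_rois_to_spots(detector.rois_, centres,
                                            max_dist_um=4.0)
    narrow_set, broad_set = centres[:n_narrow], centres[n_narrow:]

    def nearest_is_narrow(roi) -> bool:
        d_n = min(np.hypot(roi.centroid_px[0] - r, roi.centroid_px[1] - c)
                  for r, c in narrow_set)
        d_b = min(np.hypot(roi.centroid_px[0] - r, roi.centroid_px[1] - c)
                  for r, c in broad_set)
        return d_n < d_b

    narrow_areas = [r.area_um2 for r in detector.rois_.rois
                    if nearest_is_narrow(r)]
    broad_areas = [r.area_um2 for r in detector.rois_.rois
                   if not nearest_is_narrow(r)]
    return {
        "recall": float(recall),
        "precision": float(precision),
        "n_rois": len(detector.rois_),
        "narrow_mean_area_um2": (float(np.mean(narrow_areas))
                                 if narrow_areas else np.nan),
        "broad_mean_area_um2": (float(np.mean(broad_areas))
                                if broad_areas else np.nan),
        "n_frames": movie.n_frames,
    }


def als_bias_experiment(n_rois: int = 40, seed: int = 1) -> dict:
    """Amplitude bias of ALS baseline + template extraction at SNR 5.

    Traces carry slow exponential-plus-linear drift and 5-Hz trains of
    quantal transients (q = 0.09) with per-frame noise SD 0.018 (event
    SNR 5 for single quanta); the mean extraction error on true events is
    reported as a fraction of the quantal size.
    """
    proto = StimulusProtocol(conditions=("2",))
    errs = []
    for i in range(n_rois):
        gt = GroundTruth(n_sites=5, q_true=0.09, p_release={"2": 0.4},
                         noise_sd=0.018, drift_amplitude=0.15,
                         drift_tau_s=10.0, drift_slope=0.002,
                         seed=seed * 40_000 + i)
        rng = np.random.default_rng([seed, i])
        counts = simulate_release_counts(gt, proto, rng=rng)
        dff = simulate_trace(counts, gt, proto, rng=rng)
        ts = TraceSet(dff=dff, f0=np.array([1.0]), roi_ids=["roi"],
                      frame_rate_hz=proto.frame_rate_hz,
                      stim_table=proto.stim_table())
        table = extract_peaks_at_template(
            ts, template_indices=proto.stimulus_frames(),
            baseline=AlsBaseline())
        true_amp = counts["2"] * gt.q_true
        est = table["amplitude"].to_numpy()
        real = true_amp > 0
        errs.append(float(np.mean(est[real] - true_amp[real])))
    bias = float(np.mean(errs))
    return {"bias_frac_of_q": bias / 0.09, "n_rois": n_rois}


def determinism_experiment(base_dir: str | Path, seed: int = 1) -> dict:
    """Byte-identity of two pipeline runs with the same config and seed."""
    base_dir = Path(base_dir)
    outputs = ("peaks.csv", "traces.csv", "rois.csv", "quantal_fits.json",
               "quantal_summary.csv", "ground_truth.json")

    def one_run(tag: str) -> Path:
        outdir = base_dir / tag
        cfg = RunConfig(
            source="simulate", n_rois=6, render_movie=True,
            movie_shape=(96, 96), spot_peak_counts=4000.0, seed=seed,
            outdir=str(outdir), n_range=(1, 10),
            ground_truth=GroundTruth(p_release={"2": 0.4}, seed=seed),
            protocol=StimulusProtocol(conditions=("2",), inter_train_s=3.0))
        run_pipeline(cfg)
        return outdir

    dir_a = one_run("run_a")
    dir_b = one_run("run_b")
    identical = {}
    for name in outputs:
        a, b = dir_a / name, dir_b / name
        identical[name] = (a.exists() and b.exists()
                           and a.read_bytes() == b.read_bytes())
    return {"identical": all(identical.values()), "per_file": identical}


def cv_consistency_experiment(n_rois: int = 60, seed: int = 1) -> dict:
    """CV-route vs histogram-route rank agreement on shared data.

    Simulates one cell under the study conditions and checks that both
    routes order the per-condition release probability monotonically in
    calcium.
    """
    from .quantal import CvAnalysis

    proto = StimulusProtocol()
    gt = GroundTruth(seed=seed)
    table = simulate_peak_table(gt, proto, n_rois=n_rois, seed=seed)
    cv = CvAnalysis().fit(table)
    ps_hist = {c: [] for c in STUDY_P_RELEASE}
    for _, grp in table.groupby("roi_id", sort=False):
        m = QuantalHistogramModel(model="binomial", seed=seed)
        m.fit(grp["amplitude"].to_numpy(),
              grp["condition"].astype(str).to_numpy())
        for c in STUDY_P_RELEASE:
            ps_hist[c].append(m.p_release_[c])
    hist_med = {c: float(np.median(v)) for c, v in ps_hist.items()}
    order = ("0.5", "2", "4")
    return {
        "cv_p_release": cv.p_release_,
        "cv_n_sites": cv.n_sites_,
        "hist_p_release_median": hist_med,
        "cv_monotone": bool(cv.p_release_
                            and cv.p_release_[order[0]]
                            < cv.p_release_[order[1]]
                            < cv.p_release_[order[2]]),
        "hist_monotone": bool(hist_med[order[0]] < hist_med[order[1]]
                              < hist_med[order[2]]),
    }
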