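"""Synthetic glutamate-sensor data with known quantal ground truth.

Every downstream stage of the package (ROI detection, trace extraction,
peak metrics, quantal inference) is testable against movies, traces and
peak tables generated here. The forward model is trial-wise multivesicular
release: at each stimulus a number of vesicles is drawn from a binomial
(``N`` independent release sites, per-site probability ``P_R``) or Poisson
(rate ``lambda = N * P_R``) law; each vesicle contributes a fixed quantal
fluorescence increment ``q`` (dF/F units). Transients rise instantaneously
and decay mono-exponentially, so 5-Hz trains summate; additive Gaussian
noise, slow baseline drift and optional multiplicative per-train rundown
complete the trace model. Movies place each trace on a 2-D Gaussian spot
over a constant background.

The defaults are the study conditions used throughout the test-suite:
``N = 5`` sites, ``q = 0.09`` dF/F, ``P_R = 0.1 / 0.4 / 0.7`` at
0.5 / 2 / 4 mM calcium, amplitude noise SD 0.03, 25-Hz frame rate,
10 trains of 5 stimuli at 5 Hz per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .movie import FluorescenceMovie

logger = logging.getLogger(__name__)

RELEASE_MODELS = ("binomial", "poisson")


def _default_p_release() -> dict[str, float]:
    return {"0.5": 0.1, "2": 0.4, "4": 0.7}


@dataclass
class GroundTruth:
    """True quantal parameters of one simulated ROI / cell.

    Parameters
    ----------
    n_sites : int
        Number of independent release sites N (>= 1).
    q_true : float
        Quantal fluorescence increment q in dF/F units (> 0).
    p_release : mapping
        Calcium-condition label -> per-site release probability P_R in [0, 1].
        For Poisson generation the rate is ``lambda = n_sites * p_release``.
    noise_sd : float
        Additive Gaussian amplitude noise, dF/F units (>= 0).
    quantal_cv : float
        Per-vesicle amplitude variability: each vesicle contributes
        ``q_true * (1 + eps)`` with ``eps ~ N(0, quantal_cv)``, so the
        dispersion of the k-quantum level grows as ``sqrt(k)``. Default 0
        (fixed quantal amplitude).
    rundown_factor : float
        Multiplicative amplitude decay applied per train, in (0, 1].
    drift_amplitude, drift_tau_s, drift_slope : float
        Baseline drift: one slow exponential of the given amplitude and time
        constant plus a linear term (dF/F per second).
    spot_sigma_um : float
        Standard deviation of the 2-D Gaussian spatial footprint. Targeted
        sensors give narrow spots (~0.3-0.5 um), untargeted diffuse ones
        (~1.5 um).
    decay_tau_s : float
        Single-exponential decay time constant of the response kernel.
    seed : int
        Master seed; all per-ROI streams are derived from it.
    """

    n_sites: int = 5
    q_true: float = 0.09
    p_release: Mapping[str, float] = field(default_factory=_default_p_release)
    noise_sd: float = 0.03
    quantal_cv: float = 0.0
    rundown_factor: float = 1.0
    drift_amplitude: float = 0.05
    drift_tau_s: float = 20.0
    drift_slope: float = 0.0
    spot_sigma_um: float = 0.3
    decay_tau_s: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.q_true <= 0:
            raise ValueError("q_true must be positive")
        for cond, p in self.p_release.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_release[{cond!r}] must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.quantal_cv < 0:
            raise ValueError("quantal_cv must be >= 0")
        if not 0.0 < self.rundown_factor <= 1.0:
            raise ValueError("rundown_factor must lie in (0, 1]")
        if self.spot_sigma_um <= 0:
            raise ValueError("spot_sigma_um must be positive")


@dataclass
class StimulusProtocol:
    """Stimulation and acquisition timing.

    Default: three calcium conditions, each with 10 trains of 5 stimuli at
    5 Hz (50 stimuli per condition, 150 in total), imaged at 25 Hz. Trains
    start ``lead_in_s`` into each condition segment and are separated by
    ``inter_train_s`` of rest after the last stimulus of a train.
    """

    conditions: tuple[str, ...] = ("0.5", "2", "4")
    trains_per_condition: int = 10
    stimuli_per_train: int = 5
    stimulus_interval_s: float = 0.2
    frame_rate_hz: float = 25.0
    lead_in_s: float = 2.0
    inter_train_s: float = 2.0

    def __post_init__(self) -> None:
        if self.trains_per_condition < 1 or self.stimuli_per_train < 1:
            raise ValueError("trains and stimuli per train must be positive")
        if min(self.stimulus_interval_s, self.frame_rate_hz,
               self.lead_in_s, self.inter_train_s) <= 0:
            raise ValueError("all protocol timings must be positive")

    @property
    def stimuli_per_condition(self) -> int:
        return self.trains_per_condition * self.stimuli_per_train

    @property
    def train_period_s(self) -> float:
        return ((self.stimuli_per_train - 1) * self.stimulus_interval_s
                + self.inter_train_s)

    @property
    def condition_duration_s(self) -> float:
        return self.lead_in_s + self.trains_per_condition * self.train_period_s

    @property
    def frames_per_condition(self) -> int:
        return int(round(self.condition_duration_s * self.frame_rate_hz))

    @property
    def n_frames_total(self) -> int:
        return self.frames_per_condition * len(self.conditions)

    def stim_table(self) -> pd.DataFrame:
        """One row per stimulus over the concatenated condition segments.

        Columns: frame, time_s, condition, train, stimulus_index (both
        0-based within condition / train).
        """
        rows = []
        fr = self.frame_rate_hz
        for ci, cond in enumerate(self.conditions):
            seg0 = ci * self.frames_per_condition
            for tr in range(self.trains_per_condition):
                t_train = self.lead_in_s + tr * self.train_period_s
                for si in range(self.stimuli_per_train):
                    t = t_train + si * self.stimulus_interval_s
                    frame = seg0 + int(round(t * fr))
                    rows.append((frame, frame / fr, cond, tr, si))
        return pd.DataFrame(
            rows, columns=["frame", "time_s", "condition", "train",
                           "stimulus_index"])

    def stimulus_frames(self) -> np.ndarray:
        return self.stim_table()["frame"].to_numpy()


def _resolve_rng(rng: np.random.Generator | None, seed: int) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(seed)


def roi_rng(seed: int, roi_index: int) -> np.random.Generator:
    """Deterministic per-ROI substream of the master seed."""
    return np.random.default_rng([int(seed), int(roi_index)])


def simulate_release_counts(
    gt: GroundTruth,
    protocol: StimulusProtocol,
    model: str = "binomial",
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Draw per-stimulus vesicle counts for every condition.

    Returns a mapping condition -> integer array of length
    ``protocol.stimuli_per_condition``. Binomial counts are bounded by
    ``n_sites``; the Poisson rate is ``n_sites * p_release``.
    """
    if model not in RELEASE_MODELS:
        raise ValueError(
            f"unknown release model {model!r}; allowed: {RELEASE_MODELS}")
    rng = _resolve_rng(rng, gt.seed)
    n_stim = protocol.stimuli_per_condition
    counts: dict[str, np.ndarray] = {}
    for cond in protocol.conditions:
        p = gt.p_release[cond]
        if model == "binomial":
            counts[cond] = rng.binomial(gt.n_sites, p, size=n_stim)
        else:
            counts[cond] = rng.poisson(gt.n_sites * p, size=n_stim)
    return counts


def _drift(gt: GroundTruth, times_s: np.ndarray) -> np.ndarray:
    return (gt.drift_slope * times_s
            + gt.drift_amplitude * (1.0 - np.exp(-times_s / gt.drift_tau_s)))


def simulate_trace(
    counts: Mapping[str, np.ndarray] | np.ndarray,
    gt: GroundTruth,
    protocol: StimulusProtocol,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward-model a dF/F time series from vesicle counts.

    Each stimulus adds a transient of peak amplitude
    ``count * q_true * rundown_factor**train`` that decays with time constant
    ``decay_tau_s``; within a 5-Hz train successive transients summate on the
    residual of the previous ones. Slow drift and per-frame Gaussian noise of
    SD ``noise_sd`` are added on top.

    ``counts`` may be a mapping over ``protocol.conditions`` or a flat array
    covering the concatenated stimuli in protocol order.
    """
    rng = _resolve_rng(rng, gt.seed)
    stim = protocol.stim_table()
    if isinstance(counts, Mapping):
        flat = np.concatenate([np.asarray(counts[c])
                               for c in protocol.conditions])
    else:
        flat = np.asarray(counts)
    if len(flat) != len(stim):
        raise ValueError(
            f"counts length {len(flat)} does not match protocol "
            f"({len(stim)} stimuli)")

    n_frames = protocol.n_frames_total
    impulses = np.zeros(n_frames)
    amps = flat * gt.q_true
    if gt.quantal_cv > 0:
        amps = amps + (gt.q_true * gt.quantal_cv * np.sqrt(flat)
                       * rng.normal(0.0, 1.0, size=len(flat)))
    amps = amps * gt.rundown_factor ** stim["train"].to_numpy()
    np.add.at(impulses, stim["frame"].to_numpy(), amps)
    # recursive one-pole filter == instantaneous rise, exponential decay
    alpha = np.exp(-1.0 / (gt.decay_tau_s * protocol.frame_rate_hz))
    dff = lfilter([1.0], [1.0, -alpha], impulses)
    times = np.arange(n_frames) / protocol.frame_rate_hz
    dff += _drift(gt, times)
    if gt.noise_sd > 0:
        dff += rng.normal(0.0, gt.noise_sd, size=n_frames)
    return dff


def simulate_movie(
    traces: np.ndarray,
    spot_centres_px: Sequence[tuple[float, float]],
    gt: GroundTruth | Sequence[GroundTruth],
    protocol: StimulusProtocol,
    shape: tuple[int, int] = (128, 128),
    background: float = 100.0,
    pixel_size_um: float = 0.5,
    spot_peak_counts: float | Sequence[float] = 2000.0,
    shot_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> FluorescenceMovie:
    """Render per-ROI dF/F traces as Gaussian spots on a constant background.

    Each spot ``i`` contributes, at frame ``t``, an intensity
    ``spot_peak_counts[i] * (1 + traces[i, t]) * G(r; spot_sigma)`` where
    ``G`` is a unit-peak 2-D Gaussian, so the spot's own dF/F equals the
    input trace after background subtraction. Optional Poisson shot noise
    is applied to the whole frame.
    """
    traces = np.atleast_2d(np.asarray(traces))
    n_rois, n_frames = traces.shape
    centres = [(float(r), float(c)) for r, c in spot_centres_px]
    if len(centres) != n_rois:
        raise ValueError("one spot centre per trace required")
    gts = list(gt) if isinstance(gt, (list, tuple)) else [gt] * n_rois
    peaks = (list(spot_peak_counts)
             if np.ndim(spot_peak_counts) else [float(spot_peak_counts)] * n_rois)
    H, W = shape
    for r, c in centres:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"spot centre ({r}, {c}) outside frame {shape}")
    seen: set[tuple[int, int]] = set()
    for r, c in centres:
        key = (int(round(r)), int(round(c)))
        if key in seen:
            logger.warning("overlapping spot centres at %s", key)
        seen.add(key)

    data = np.full((n_frames, H, W), float(background), dtype=np.float32)
    for (r0, c0), g, peak, trace in zip(centres, gts, peaks, traces):
        sigma_px = g.spot_sigma_um / pixel_size_um
        half = max(2, int(np.ceil(4 * sigma_px)))
        r_lo, r_hi = max(0, int(r0) - half), min(H, int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(W, int(c0) + half + 1)
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        kernel = np.exp(-(rr**2 + cc**2) / (2 * sigma_px**2)).astype(np.float32)
        amp = (peak * (1.0 + trace)).astype(np.float32)
        data[:, r_lo:r_hi, c_lo:c_hi] += amp[:, None, None] * kernel[None, :, :]
    if shot_noise:
        rng = _resolve_rng(rng, gts[0].seed)
        data = rng.poisson(np.clip(data, 0, None)).astype(np.float32)
    np.clip(data, 0, None, out=data)
    stim = protocol.stimulus_frames()
    return FluorescenceMovie(
        data=data,
        frame_rate_hz=protocol.frame_rate_hz,
        pixel_size_um=pixel_size_um,
        stimulus_frames=stim[stim < n_frames],
    )


def simulate_epsc_trains(
    gt: GroundTruth,
    protocol: StimulusProtocol,
    depression_per_stimulus: float = 0.9,
    counts: Mapping[str, np.ndarray] | None = None,
    unit_pa: float = 10.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Paired EPSC amplitude trains for the optical recordings.

    EPSC amplitude at within-train stimulus ``s`` (0-based) is proportional
    to the total released quanta at that stimulus times
    ``depression_per_stimulus**s``, emulating short-term depression of the
    postsynaptic response.
    """
    if not 0.0 < depression_per_stimulus <= 1.0:
        raise ValueError("depression_per_stimulus must lie in (0, 1]")
    if counts is None:
        counts = simulate_release_counts(gt, protocol,
                                         rng=_resolve_rng(rng, gt.seed))
    stim = protocol.stim_table()
    flat = np.concatenate([np.asarray(counts[c]) for c in protocol.conditions])
    amp = (flat * unit_pa
           * depression_per_stimulus ** stim["stimulus_index"].to_numpy())
    out = stim[["condition", "train", "stimulus_index"]].copy()
    out["amplitude_pa"] = amp
    return out


def simulate_peak_table(
    gt: GroundTruth,
    protocol: StimulusProtocol,
    n_rois: int = 1,
    model: str = "binomial",
    failure_threshold: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Amplitude-level forward model: a tidy peak table for many ROIs.

    Skips the trace stage: per-stimulus amplitude is
    ``count * q_true * rundown**train`` plus Gaussian amplitude noise of SD
    ``noise_sd``; amplitudes below the failure threshold (default
    ``2 * noise_sd``, mirroring the extraction stage) are pinned to exactly
    0, as are all failures. Ground-truth counts are kept in a ``true_count``
    column. Each ROI uses a deterministic substream of the master seed.
    """
    if failure_threshold is None:
        failure_threshold = 2.0 * gt.noise_sd
    master = gt.seed if seed is None else seed
    frames = []
    for roi in range(n_rois):
        rng = roi_rng(master, roi)
        counts = simulate_release_counts(gt, protocol, model=model, rng=rng)
        stim = protocol.stim_table()
        flat = np.concatenate([np.asarray(counts[c])
                               for c in protocol.conditions])
        amp = flat * gt.q_true
        if gt.quantal_cv > 0:
            amp = amp + (gt.q_true * gt.quantal_cv * np.sqrt(flat)
                         * rng.normal(0.0, 1.0, size=len(amp)))
        amp = amp * gt.rundown_factor ** stim["train"].to_numpy()
        if gt.noise_sd > 0:
            amp = amp + rng.normal(0.0, gt.noise_sd, size=len(amp))
        amp = np.where(amp < failure_threshold, 0.0, amp)
        df = stim[["condition", "train", "stimulus_index"]].copy()
        df.insert(0, "roi_id", f"roi_{roi:03d}")
        df["amplitude"] = amp
        df["is_failure"] = amp == 0.0
        df["true_count"] = flat
        df["excluded"] = False
        df["reason"] = ""
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# writers

def write_traces_csv(
    dff: np.ndarray,
    roi_ids: Sequence[str],
    protocol: StimulusProtocol,
    path: str | Path,
) -> Path:
    """Long-format trace CSV: time_s, roi_id, dff, condition annotation."""
    dff = np.atleast_2d(dff)
    n_rois, n_frames = dff.shape
    times = np.arange(n_frames) / protocol.frame_rate_hz
    cond_of_frame = np.repeat(list(protocol.conditions),
                              protocol.frames_per_condition)
    if len(cond_of_frame) < n_frames:  # trailing frames keep last condition
        pad = n_frames - len(cond_of_frame)
        cond_of_frame = np.concatenate(
            [cond_of_frame, [protocol.conditions[-1]] * pad])
    rows = {
        "time_s": np.tile(times, n_rois),
        "roi_id": np.repeat(list(roi_ids), n_frames),
        "dff": dff.ravel(),
        "condition": np.tile(cond_of_frame[:n_frames], n_rois),
    }
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_traces_csv(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Inverse of :func:`write_traces_csv`; returns (dff, roi_ids, times)."""
    df = pd.read_csv(path, dtype={"roi_id": str})
    roi_ids = list(dict.fromkeys(df["roi_id"]))
    times = df[df["roi_id"] == roi_ids[0]]["time_s"].to_numpy()
    dff = np.stack([df[df["roi_id"] == r]["dff"].to_numpy() for r in roi_ids])
    return dff, roi_ids, times


def write_ground_truth_json(
    gt: GroundTruth, protocol: StimulusProtocol, path: str | Path
) -> Path:
    path = Path(path)
    payload = {"ground_truth": asdict(gt), "protocol": asdict(protocol)}
    payload["ground_truth"]["p_release"] = dict(gt.p_release)
    path.write_text(json.dumps(payload, indent=1))
    return path
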