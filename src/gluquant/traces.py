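"""Background correction and dF/F trace extraction.

Converts a movie plus ROI geometry into per-ROI fluorescence time series in
dF/F units: a background region (the dimmest stimulus-independent patch of
the field) is subtracted frame-wise, the baseline F0 is the median
background-subtracted fluorescence over a pre-stimulus window, and
``dF/F_j = (F_j - F0) / F0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import FluorescenceMovie


@dataclass
class TraceSet:
    """Per-ROI dF/F time series with protocol annotation.

    Attributes
    ----------
    dff : ndarray, shape (n_rois, n_frames)
    f : ndarray or None
        Background-subtracted fluorescence in counts (same shape); kept for
        baseline-stability diagnostics.
    f0 : ndarray, shape (n_rois,)
        Baseline fluorescence per ROI, counts.
    roi_ids : list of str
    frame_rate_hz : float
    stim_table : DataFrame
        One row per stimulus: frame, condition, train, stimulus_index.
    valid : ndarray of bool
        False for ROIs with non-positive F0 (excluded downstream).
    """

    dff: np.ndarray
    f0: np.ndarray
    roi_ids: list[str]
    frame_rate_hz: float
    stim_table: pd.DataFrame
    f: np.ndarray | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    background_roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.f0 = np.atleast_1d(np.asarray(self.f0, dtype=float))
        if self.valid is None:
            self.valid = np.ones(self.dff.shape[0], dtype=bool)

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


def _disk_mask(radius_px: int) -> np.ndarray:
    r = np.arange(-radius_px, radius_px + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius_px**2


def select_background_roi(
    movie: FluorescenceMovie,
    diameter_um: float = 1.0,
    n_candidates: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the dimmest circular region without stimulus-locked modulation.

    Scans the temporal-mean image with a circular footprint of the given
    diameter, takes the ``n_candidates`` dimmest centres, and returns the
    first whose mean time series shows no stimulus-locked increase (tested
    against its robust noise). If every candidate is modulated, falls back
    to the global minimum with a warning.

    Returns
    -------
    mask : boolean image of the chosen region
    series : frame-wise mean intensity of the region
    """
    px = movie.pixel_size_um
    radius_px = max(1, int(round(diameter_um / 2.0 / px)))
    footprint = _disk_mask(radius_px)
    mean_img = movie.data.mean(axis=0)
    # mean over the disk at every centre; exclude rim where the disk clips
    disk_mean = ndimage.convolve(mean_img, footprint / footprint.sum(),
                                 mode="constant", cval=np.inf)
    disk_mean[:radius_px, :] = np.inf
    disk_mean[-radius_px:, :] = np.inf
    disk_mean[:, :radius_px] = np.inf
    disk_mean[:, -radius_px:] = np.inf

    order = np.argsort(disk_mean, axis=None)[:n_candidates]
    centres = np.column_stack(np.unravel_index(order, disk_mean.shape))

    def region_series(centre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = np.zeros(mean_img.shape, dtype=bool)
        r0, c0 = centre
        mask[r0 - radius_px:r0 + radius_px + 1,
             c0 - radius_px:c0 + radius_px + 1] = footprint
        return mask, movie.data[:, mask].mean(axis=1)

    stim = movie.stimulus_frames
    for centre in centres:
        mask, series = region_series(centre)
        if stim.size == 0 or not _is_stimulus_modulated(series, stim):
            return mask, series
    warnings.warn("all candidate background regions are stimulus-modulated; "
                  "falling back to the global-minimum region")
    return region_series(centres[0])


def _is_stimulus_modulated(series: np.ndarray, stim_frames: np.ndarray,
                           post_frames: int = 3) -> bool:
    """Median post-stimulus increment exceeding 3x robust noise."""
    med = np.median(series)
    noise = 1.4826 * np.median(np.abs(series - med))
    if noise == 0:
        noise = np.finfo(float).tiny
    deltas = []
    for f in stim_frames:
        if f - 1 < 0 or f + post_frames > len(series):
            continue
        deltas.append(series[f:f + post_frames].max() - series[f - 1])
    if not deltas:
        return False
    return bool(np.median(deltas) > 3.0 * noise)


def compute_dff(
    raw: np.ndarray,
    background: np.ndarray,
    baseline_window: slice | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Background-subtract frame-wise and normalise to the baseline median.

    ``F_j = raw_j - background_j``; ``F0 = median(F[baseline_window])``;
    ``dF/F_j = (F_j - F0) / F0``. ROIs with ``F0 <= 0`` are flagged invalid
    and their traces set to NaN.

    Accepts a single trace (1-D) or a stack (n_rois, n_frames); returns
    ``(dff, f0, valid)`` with matching leading dimension.
    """
    raw2 = np.atleast_2d(np.asarray(raw, dtype=float))
    background = np.asarray(background, dtype=float)
    if background.shape[-1] != raw2.shape[-1]:
        raise ValueError("background length must match the traces")
    f = raw2 - background[None, :]
    f0 = np.median(f[:, baseline_window], axis=1)
    valid = f0 > 0
    safe_f0 = np.where(valid, f0, np.nan)
    dff = (f - safe_f0[:, None]) / safe_f0[:, None]
    if np.ndim(raw) == 1:
        return dff[0], f0[0], valid[0]
    return dff, f0, valid


def extract_traces(
    movie: FluorescenceMovie,
    roi_masks: list[np.ndarray] | np.ndarray,
    roi_ids: list[str],
    stim_table: pd.DataFrame,
    background: np.ndarray | None = None,
    baseline_window: slice | None = None,
) -> TraceSet:
    """Movie + ROI masks -> background-corrected dF/F :class:`TraceSet`.

    The default baseline window is every frame before the first stimulus.
    """
    if background is None:
        bg_mask, background = select_background_roi(movie)
    else:
        bg_mask = None
    if baseline_window is None:
        first = (int(stim_table["frame"].min())
                 if len(stim_table) else movie.n_frames)
        baseline_window = slice(0, max(2, first))
    raw = np.stack([movie.data[:, m].mean(axis=1) for m in roi_masks])
    dff, f0, valid = compute_dff(raw, background, baseline_window)
    f = raw - background[None, :]
    return TraceSet(dff=dff, f0=f0, roi_ids=list(roi_ids),
                    frame_rate_hz=movie.frame_rate_hz,
                    stim_table=stim_table.reset_index(drop=True), f=f,
                    valid=valid, background_roi=bg_mask)


def f0_stability(
    traceset: TraceSet, pre_frames: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-train baseline F0 and the fractional drift over the recording.

    F0 for each train is the median background-subtracted fluorescence over
    the ``pre_frames`` frames preceding the train's first stimulus. The
    drift fraction per ROI is ``(F0_last - F0_first) / F0_first``.
    """
    if traceset.f is None:
        raise ValueError("TraceSet has no raw fluorescence for F0 analysis")
    stim = traceset.stim_table
    train_starts = (stim.groupby(["condition", "train"], sort=False)["frame"]
                    .min().to_numpy())
    train_starts = np.sort(train_starts)
    if len(train_starts) < 2:
        raise ValueError("f0_stability requires at least 2 trains")
    rows = []
    per_roi_f0 = np.empty((traceset.n_rois, len(train_starts)))
    for ti, f_start in enumerate(train_starts):
        lo = max(0, int(f_start) - pre_frames)
        window = traceset.f[:, lo:int(f_start)]
        f0_t = np.median(window, axis=1)
        per_roi_f0[:, ti] = f0_t
        for ri, roi in enumerate(traceset.roi_ids):
            rows.append((roi, ti, f0_t[ri]))
    table = pd.DataFrame(rows, columns=["roi_id", "train_index", "f0"])
    first = per_roi_f0[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        drift = (per_roi_f0[:, -1] - first) / first
    return table, drift
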