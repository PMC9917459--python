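"""Responsive-ROI detection by tile statistics and contiguous merging.

The field of view is divided into 4x4-pixel tiles; a tile is accepted when
its mean-intensity time series shows more than ``min_peaks`` positive-going
stimulus-locked transients, each with dF/F of at least ``min_event_dff``
and signal-to-noise of at least ``min_snr``. Accepted tiles that touch
edge-to-edge (4-connectivity) are merged into composite ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from sklearn.base import BaseEstimator

from .movie import FluorescenceMovie
from .peaks import als_baseline, robust_noise_sd

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class TileCriteria:
    """Acceptance thresholds for a single tile.

    ``min_peaks`` is a strict threshold: a tile needs *more than*
    ``min_peaks`` qualifying transients.
    """

    tile_size_px: int = 4
    min_event_dff: float = 0.10
    min_snr: float = 3.0
    min_peaks: int = 20

    def __post_init__(self) -> None:
        if min(self.tile_size_px, self.min_event_dff, self.min_snr,
               self.min_peaks) <= 0:
            raise ValueError("all tile criteria must be positive")


@dataclass
class Roi:
    """Composite ROI: a 4-connected set of accepted tiles."""

    id: str
    tiles: list[tuple[int, int]]
    tile_size_px: int
    pixel_size_um: float
    centroid_px: tuple[float, float]

    @property
    def tile_count(self) -> int:
        return len(self.tiles)

    @property
    def n_pixels(self) -> int:
        return self.tile_count * self.tile_size_px**2

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size_um**2

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        ts = self.tile_size_px
        for ti, tj in self.tiles:
            m[ti * ts:(ti + 1) * ts, tj * ts:(tj + 1) * ts] = True
        return m


@dataclass
class RoiSet:
    rois: list[Roi]
    shape: tuple[int, int]
    pixel_size_um: float
    tile_size_px: int = 4
    tile_stats: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.rois)

    def masks(self) -> list[np.ndarray]:
        return [roi.mask(self.shape) for roi in self.rois]

    def ids(self) -> list[str]:
        return [roi.id for roi in self.rois]


def tile_mean_traces(movie: FluorescenceMovie, tile_size_px: int = 4
                     ) -> np.ndarray:
    """Mean-intensity time series of every full tile, shape (T, Ht, Wt).

    Edge rows/columns that do not fill a whole tile are discarded so that
    tile statistics stay homogeneous.
    """
    T, H, W = movie.shape
    ts = tile_size_px
    Ht, Wt = H // ts, W // ts
    if Ht == 0 or Wt == 0:
        raise ValueError("movie smaller than one tile")
    data = movie.data[:, :Ht * ts, :Wt * ts]
    return data.reshape(T, Ht, ts, Wt, ts).mean(axis=(2, 4))


def _tile_event_count(
    dff: np.ndarray,
    stim_frames: np.ndarray,
    criteria: TileCriteria,
    smoothness: float = 1e4,
    post_frames: int = 3,
    decay_frames: int = 12,
) -> tuple[int, float]:
    """Count stimulus-aligned transients passing amplitude and SNR cuts.

    The noise SD is estimated from quiet frames only (outside stimulus
    windows and their decay tails); with 5-Hz trains the response tails
    occupy most of the recording and would otherwise inflate the estimate.
    """
    corrected = dff - als_baseline(dff, smoothness=smoothness)
    quiet = np.ones(len(corrected), dtype=bool)
    for f in stim_frames:
        quiet[max(0, f - 1):f + decay_frames] = False
    sample = corrected[quiet] if quiet.sum() >= 30 else corrected
    noise = robust_noise_sd(sample)
    if noise == 0:
        return 0, 0.0
    n_events = 0
    for f in stim_frames:
        if f < 1 or f + post_frames > len(corrected):
            continue
        amp = corrected[f:f + post_frames].max() - corrected[f - 1]
        if amp >= criteria.min_event_dff and amp / noise >= criteria.min_snr:
            n_events += 1
    return n_events, noise


def scan_tiles(
    movie: FluorescenceMovie,
    criteria: TileCriteria | None = None,
    baseline_frames: int | None = None,
) -> tuple[list[tuple[int, int]], pd.DataFrame]:
    """Scan the tile grid and return accepted tiles plus per-tile stats.

    Tile dF/F is computed on raw tile means against the median of the
    pre-stimulus window; events are stimulus-aligned increments over the
    preceding frame after ALS drift removal. Tiles whose maximum dF/F never
    reaches ``min_event_dff`` are screened out before the per-tile baseline
    fit, which keeps the scan fast on large fields.
    """
    criteria = criteria or TileCriteria()
    if movie.n_frames < 2:
        raise ValueError("movie must have at least 2 frames")
    stim = movie.stimulus_frames
    if stim.size == 0:
        raise ValueError("movie has no stimulus frames")
    if movie.n_frames <= int(stim[0]):
        raise ValueError("movie shorter than one stimulus train")
    tiles = tile_mean_traces(movie, criteria.tile_size_px)
    T, Ht, Wt = tiles.shape
    if baseline_frames is None:
        baseline_frames = max(2, int(stim[0]))
    f0 = np.median(tiles[:baseline_frames], axis=0)
    f0 = np.where(f0 > 0, f0, np.nan)
    dff = (tiles - f0[None]) / f0[None]

    candidate = np.nanmax(dff, axis=0) >= criteria.min_event_dff
    accepted: list[tuple[int, int]] = []
    rows = []
    for ti, tj in np.argwhere(candidate):
        n_events, noise = _tile_event_count(dff[:, ti, tj], stim, criteria)
        ok = n_events > criteria.min_peaks
        rows.append((ti, tj, n_events, noise, ok))
        if ok:
            accepted.append((int(ti), int(tj)))
    stats = pd.DataFrame(
        rows, columns=["tile_row", "tile_col", "n_events", "noise_sd",
                       "accepted"])
    return accepted, stats


def merge_contiguous(
    tiles: list[tuple[int, int]],
    shape: tuple[int, int],
    pixel_size_um: float,
    tile_size_px: int = 4,
) -> RoiSet:
    """Merge 4-connected accepted tiles into composite ROIs.

    Composite area equals ``tile_count * tile_size_px^2 * pixel_size_um^2``;
    ROIs are disjoint by construction and ids are stable (raster order of
    the component's upper-left tile).
    """
    Ht, Wt = shape[0] // tile_size_px, shape[1] // tile_size_px
    grid = np.zeros((Ht, Wt), dtype=bool)
    for ti, tj in tiles:
        grid[ti, tj] = True
    labels, n = ndimage.label(grid, structure=FOUR_CONNECTED)
    comps: list[list[tuple[int, int]]] = []
    for lab in range(1, n + 1):
        comp = [tuple(int(v) for v in rc) for rc in np.argwhere(labels == lab)]
        comps.append(sorted(comp))
    comps.sort(key=lambda c: c[0])
    rois = []
    for i, comp in enumerate(comps):
        centre = np.mean([[(ti + 0.5) * tile_size_px,
                           (tj + 0.5) * tile_size_px]
                          for ti, tj in comp], axis=0)
        rois.append(Roi(id=f"roi_{i:03d}", tiles=comp,
                        tile_size_px=tile_size_px,
                        pixel_size_um=pixel_size_um,
                        centroid_px=(float(centre[0]), float(centre[1]))))
    return RoiSet(rois=rois, shape=shape, pixel_size_um=pixel_size_um,
                  tile_size_px=tile_size_px)


def roi_count_and_sizes(roiset: RoiSet) -> dict:
    """Count and per-composite areas after merging."""
    areas = [roi.area_um2 for roi in roiset.rois]
    return {
        "count": len(areas),
        "areas_um2": areas,
        "mean_area_um2": float(np.mean(areas)) if areas else None,
    }


class TileRoiDetector(BaseEstimator):
    """sklearn-style detector: ``fit(movie)`` locates responsive ROIs.

    Parameters mirror :class:`TileCriteria`. After fitting, ``tiles_`` holds
    the accepted tile coordinates, ``rois_`` the merged :class:`RoiSet` and
    ``tile_stats_`` the per-candidate-tile diagnostics.
    """

    def __init__(self, tile_size_px: int = 4, min_event_dff: float = 0.10,
                 min_snr: float = 3.0, min_peaks: int = 20):
        self.tile_size_px = tile_size_px
        self.min_event_dff = min_event_dff
        self.min_snr = min_snr
        self.min_peaks = min_peaks

    def criteria(self) -> TileCriteria:
        return TileCriteria(self.tile_size_px, self.min_event_dff,
                            self.min_snr, self.min_peaks)

    def fit(self, movie: FluorescenceMovie, y=None) -> "TileRoiDetector":
        tiles, stats = scan_tiles(movie, self.criteria())
        self.tiles_ = tiles
        self.tile_stats_ = stats
        self.rois_ = merge_contiguous(tiles, movie.shape[1:],
                                      movie.pixel_size_um, self.tile_size_px)
        self.rois_.tile_stats = stats
        return self


def match_rois_to_spots(
    roiset: RoiSet,
    centres_px: list[tuple[float, float]],
    max_dist_um: float = 2.0,
) -> tuple[float, float]:
    """Recall and precision of detected composites against planted spots.

    A spot is recovered when some composite covers it or has its centroid
    within ``max_dist_um``; a composite is a true positive when it matches
    some spot the same way.
    """
    if not centres_px:
        raise ValueError("no planted spots given")
    px = roiset.pixel_size_um

    def hit(roi: Roi, centre: tuple[float, float]) -> bool:
        d = np.hypot(roi.centroid_px[0] - centre[0],
                     roi.centroid_px[1] - centre[1]) * px
        if d <= max_dist_um:
            return True
        m = roi.mask(roiset.shape)
        r, c = int(round(centre[0])), int(round(centre[1]))
        return bool(0 <= r < roiset.shape[0] and 0 <= c < roiset.shape[1]
                    and m[r, c])

    recalled = sum(any(hit(roi, ctr) for roi in roiset.rois)
                   for ctr in centres_px)
    if roiset.rois:
        true_pos = sum(any(hit(roi, ctr) for ctr in centres_px)
                       for roi in roiset.rois)
        precision = true_pos / len(roiset.rois)
    else:
        precision = 0.0
    return recalled / len(centres_px), precision


def write_label_mask(roiset: RoiSet, path: str | Path) -> Path:
    """Write the ROI geometry as a labelled 16-bit TIFF."""
    labels = np.zeros(roiset.shape, dtype=np.uint16)
    for i, roi in enumerate(roiset.rois, start=1):
        labels[roi.mask(roiset.shape)] = i
    path = Path(path)
    tifffile.imwrite(path, labels)
    return path


def write_roi_csv(roiset: RoiSet, path: str | Path) -> Path:
    rows = [(roi.id, roi.centroid_px[0], roi.centroid_px[1], roi.n_pixels,
             roi.area_um2) for roi in roiset.rois]
    df = pd.DataFrame(rows, columns=["roi_id", "centroid_row_px",
                                     "centroid_col_px", "n_pixels",
                                     "area_um2"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path
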