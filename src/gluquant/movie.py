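"""Fluorescence movie container and TIFF input/output.

A movie is a (frame, row, column) stack of camera intensities together with
the acquisition frame rate, the pixel size, and the frame indices at which
stimuli were delivered. Multi-frame TIFF is the interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class FluorescenceMovie:
    """Intensity stack with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_frames, height, width)
        Camera intensities in counts; must be non-negative.
    frame_rate_hz : float
        Acquisition rate in frames per second.
    pixel_size_um : float
        Linear pixel size in micrometres.
    stimulus_frames : ndarray of int
        Frame indices of stimulus delivery, strictly increasing and within
        the movie.
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    stimulus_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (frame, row, column)")
        if np.min(self.data) < 0:
            raise ValueError("movie intensities must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.stimulus_frames = np.asarray(self.stimulus_frames, dtype=int)
        if self.stimulus_frames.size:
            if np.any(np.diff(self.stimulus_frames) <= 0):
                raise ValueError("stimulus_frames must be strictly increasing")
            if (self.stimulus_frames[0] < 0
                    or self.stimulus_frames[-1] >= self.n_frames):
                raise ValueError("stimulus_frames out of movie range")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def write_movie_tiff(movie: FluorescenceMovie, path: str | Path) -> Path:
    """Write a movie as a multi-frame TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.data, dtype=np.float32))
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        "stimulus_frames": [int(f) for f in movie.stimulus_frames],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_movie_tiff(path: str | Path) -> FluorescenceMovie:
    """Read a movie written by :func:`write_movie_tiff`."""
    path = Path(path)
    data = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"frame_rate_hz": 25.0, "pixel_size_um": 1.0, "stimulus_frames": []}
    return FluorescenceMovie(
        data=data,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        stimulus_frames=np.asarray(meta["stimulus_frames"], dtype=int),
    )
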