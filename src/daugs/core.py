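"""Core domain containers for dynamic perfusion segmentation.

A *perfusion series* is one short-axis slice imaged repeatedly during the
first pass of a contrast bolus: a 2D+time intensity volume with pixel
spacing and frame-time metadata.  Segmentation assigns each pixel one of
three classes: background, left-ventricular (LV) myocardium, or bloodpool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Label codes (fixed convention throughout the package).
BACKGROUND = 0
MYOCARDIUM = 1
BLOODPOOL = 2

LABEL_CODES = (BACKGROUND, MYOCARDIUM, BLOODPOOL)
N_CLASSES = 3


@dataclass
class PerfusionSeries:
    """One slice's 2D+time intensity volume with acquisition metadata.

    Parameters
    ----------
    intensities : ndarray, shape (H, W, T)
        Pixel intensities; finite.  After preprocessing, values lie in [0, 1].
    pixel_spacing_mm : tuple of float
        (row, column) spacing in millimetres.
    frame_times_s : ndarray, shape (T,)
        Acquisition time of each frame in seconds, strictly increasing.
    heart_center : tuple of float
        (row, col) of the heart in pixel coordinates; the crop anchor.
    series_id : str
        Stable identifier used in logs and reports.
    """

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    frame_times_s: np.ndarray | None = None
    heart_center: tuple[float, float] | None = None
    series_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be H x W x T, got shape {self.intensities.shape}"
            )
        if self.intensities.shape[2] < 2:
            raise ValueError("a perfusion series needs at least 2 frames")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.intensities.shape[2], dtype=float)
        else:
            self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
            if self.frame_times_s.shape != (self.intensities.shape[2],):
                raise ValueError("frame_times_s length must match frame count")
            if np.any(np.diff(self.frame_times_s) <= 0):
                raise ValueError("frame_times_s must be strictly increasing")
        if self.heart_center is None:
            h, w = self.intensities.shape[:2]
            self.heart_center = ((h - 1) / 2.0, (w - 1) / 2.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[2]

    def with_intensities(self, intensities: np.ndarray, **kw) -> "PerfusionSeries":
        """Copy of this series with new intensities (metadata preserved)."""
        return replace(self, intensities=np.asarray(intensities, float), **kw)


@dataclass
class LabelMask:
    """Per-pixel 3-class segmentation (ground truth or prediction)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-coded")
        bad = ~np.isin(self.labels, LABEL_CODES)
        if bad.any():
            raise ValueError(
                f"labels contain codes outside {LABEL_CODES}: "
                f"{np.unique(self.labels[bad])}"
            )
        self.labels = self.labels.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def n_pixels(self, code: int) -> int:
        return int(np.count_nonzero(self.labels == code))

    def one_hot(self) -> np.ndarray:
        """H x W x 3 one-hot encoding (float)."""
        out = np.zeros(self.labels.shape + (N_CLASSES,), dtype=np.float64)
        for c in LABEL_CODES:
            out[..., c] = self.labels == c
        return out


def as_labels(mask) -> np.ndarray:
    """Coerce a LabelMask or integer array to a validated 2D label array."""
    if isinstance(mask, LabelMask):
        return mask.labels
    return LabelMask(np.asarray(mask)).labels
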