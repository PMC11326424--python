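"""Space-time patch decomposition and recombination.

The analysis unit is a *space-time patch*: a small spatial window extended
over all time frames.  A spatially sliding window with a configurable
stride decomposes a series into overlapping patches; after patch-level
inference the per-pixel class probabilities are averaged over all covering
patches, while the raw per-patch myocardium probabilities are retained in a
:class:`PatchProbabilityStack` — the disagreement among them is the
substrate of the uncertainty map.

Strides: half the patch size during training, a quarter of the patch size
at inference (small stride = dense overlap, pixels covered by many patches).
Windows that would overrun the image are clamped to end flush with the
border, guaranteeing full coverage without padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelMask, MYOCARDIUM, N_CLASSES, PerfusionSeries

__all__ = [
    "PatchGrid",
    "PatchProbabilityStack",
    "build_grid",
    "decompose",
    "recombine",
    "to_mask",
]


@dataclass(frozen=True)
class PatchGrid:
    """Sliding-window layout: patch size plus row-major top-left origins."""

    patch_size: int
    stride: int
    origins: tuple[tuple[int, int], ...]
    image_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return len(self.origins)

    def coverage_count(self) -> np.ndarray:
        """H x W map of how many patches cover each pixel (>= 1 everywhere)."""
        cov = np.zeros(self.image_shape, dtype=np.int32)
        p = self.patch_size
        for r, c in self.origins:
            cov[r : r + p, c : c + p] += 1
        return cov


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    pos = list(range(0, extent - patch + 1, stride))
    last = extent - patch
    if pos[-1] != last:  # clamp a final window flush with the border
        pos.append(last)
    return pos


def build_grid(
    image_shape: tuple[int, int], patch_size: int, stride: int
) -> PatchGrid:
    """Sliding-window grid with full coverage of an H x W frame."""
    h, w = image_shape
    if patch_size > min(h, w):
        raise ValueError(
            f"patch_size {patch_size} exceeds image extent {image_shape}"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    origins = tuple(
        (r, c)
        for r in _axis_origins(h, patch_size, stride)
        for c in _axis_origins(w, patch_size, stride)
    )
    return PatchGrid(patch_size, stride, origins, (h, w))


def decompose(series: PerfusionSeries, grid: PatchGrid) -> np.ndarray:
    """Extract space-time patches; shape (n_patches, T, patch, patch).

    Patches are exact copies of the windows, ordered as ``grid.origins``.
    The time axis comes first within each patch so frames stack naturally
    as network input channels.
    """
    if series.shape[:2] != grid.image_shape:
        raise ValueError(
            f"series shape {series.shape[:2]} does not match grid "
            f"{grid.image_shape}"
        )
    p = grid.patch_size
    vol = np.moveaxis(series.intensities, 2, 0)  # T, H, W
    return np.stack([vol[:, r : r + p, c : c + p] for r, c in grid.origins])


@dataclass(frozen=True)
class PatchProbabilityStack:
    """Raw per-patch myocardium probabilities, pixel-aligned via the grid.

    ``patch_myo[i]`` is the myocardium-probability map of the i-th patch;
    the set of values covering pixel (r, c) is recovered through the grid's
    membership structure.
    """

    grid: PatchGrid
    patch_myo: np.ndarray  # (n_patches, patch, patch), values in [0, 1]

    def __post_init__(self) -> None:
        pm = np.asarray(self.patch_myo, dtype=np.float64)
        if pm.shape != (self.grid.n_patches, self.grid.patch_size, self.grid.patch_size):
            raise ValueError(
                f"patch_myo shape {pm.shape} inconsistent with grid "
                f"({self.grid.n_patches} patches of {self.grid.patch_size}px)"
            )
        if pm.size and (pm.min() < -1e-9 or pm.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "patch_myo", np.clip(pm, 0.0, 1.0))

    def probabilities_at(self, row: int, col: int) -> np.ndarray:
        """All covering-patch myocardium probabilities for one pixel."""
        p = self.grid.patch_size
        vals = [
            self.patch_myo[i, row - r, col - c]
            for i, (r, c) in enumerate(self.grid.origins)
            if r <= row < r + p and c <= col < c + p
        ]
        return np.array(vals)

    def moment_maps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-pixel (sum, sum of squares, count) over covering patches."""
        h, w = self.grid.image_shape
        s = np.zeros((h, w))
        s2 = np.zeros((h, w))
        n = np.zeros((h, w))
        p = self.grid.patch_size
        for i, (r, c) in enumerate(self.grid.origins):
            blk = self.patch_myo[i]
            s[r : r + p, c : c + p] += blk
            s2[r : r + p, c : c + p] += blk * blk
            n[r : r + p, c : c + p] += 1.0
        return s, s2, n


def recombine(
    patch_probs: np.ndarray | list, grid: PatchGrid
) -> tuple[np.ndarray, PatchProbabilityStack]:
    """Average patch-level class probabilities over covering patches.

    Parameters
    ----------
    patch_probs : array-like, shape (n_patches, patch, patch, 3)
        Per-patch softmax maps (each pixel's 3 values sum to 1).
    grid : PatchGrid

    Returns
    -------
    probs : ndarray, shape (H, W, 3)
        Arithmetic mean of class probabilities over covering patches.
    stack : PatchProbabilityStack
        The raw per-patch myocardium probabilities for uncertainty mapping.
    """
    pp = np.asarray(patch_probs, dtype=np.float64)
    expect = (grid.n_patches, grid.patch_size, grid.patch_size, N_CLASSES)
    if pp.shape != expect:
        raise ValueError(f"patch_probs shape {pp.shape}, expected {expect}")
    h, w = grid.image_shape
    acc = np.zeros((h, w, N_CLASSES))
    cov = np.zeros((h, w))
    p = grid.patch_size
    for i, (r, c) in enumerate(grid.origins):
        acc[r : r + p, c : c + p, :] += pp[i]
        cov[r : r + p, c : c + p] += 1.0
    if cov.min() < 1:
        raise ValueError("grid does not cover every pixel")
    probs = acc / cov[:, :, None]
    stack = PatchProbabilityStack(grid, pp[..., MYOCARDIUM])
    return probs, stack


def to_mask(probs: np.ndarray) -> LabelMask:
    """Per-pixel argmax decision; ties break toward the lower class code."""
    pr = np.asarray(probs, dtype=np.float64)
    if pr.ndim != 3 or pr.shape[2] != N_CLASSES:
        raise ValueError(f"expected H x W x {N_CLASSES} probabilities")
    return LabelMask(np.argmax(pr, axis=2).astype(np.int8))
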