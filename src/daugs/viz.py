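"""Report graphics: segmentation panels with their uncertainty maps.

U-maps are always displayed on the fixed [0, 0.5] colour scale — the
analytic range of the per-pixel standard deviation — so panels from
different cases and models are visually comparable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import BLOODPOOL, MYOCARDIUM, LabelMask, PerfusionSeries

UMAP_DISPLAY_RANGE = (0.0, 0.5)


def plot_solution_panel(series: PerfusionSeries, solution, truth=None,
                        frame: int | None = None, out_path=None):
    """Image + predicted contours + U-map for one segmentation solution.

    ``frame`` defaults to the brightest frame (peak enhancement).  Returns
    the matplotlib figure; writes a PNG when ``out_path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if frame is None:
        frame = int(series.intensities.sum(axis=(0, 1)).argmax())
    img = series.intensities[:, :, frame]

    n_cols = 3 if truth is not None else 2
    fig, axes = plt.subplots(1, n_cols, figsize=(3 * n_cols, 3.2))
    axes[0].imshow(img, cmap="gray", interpolation="nearest")
    axes[0].contour(solution.mask.labels == MYOCARDIUM, levels=[0.5],
                    colors="tab:orange", linewidths=1.0)
    axes[0].contour(solution.mask.labels == BLOODPOOL, levels=[0.5],
                    colors="tab:cyan", linewidths=0.8)
    axes[0].set_title(
        f"{series.series_id}\n{solution.member_id}  Upp={solution.upp:.4f}",
        fontsize=8,
    )
    im = axes[1].imshow(solution.umap, cmap="inferno",
                        vmin=UMAP_DISPLAY_RANGE[0], vmax=UMAP_DISPLAY_RANGE[1],
                        interpolation="nearest")
    axes[1].set_title("U-map [0, 0.5]", fontsize=8)
    fig.colorbar(im, ax=axes[1], fraction=0.046)
    if truth is not None:
        axes[2].imshow(img, cmap="gray", interpolation="nearest")
        axes[2].contour(truth.labels == MYOCARDIUM, levels=[0.5],
                        colors="tab:green", linewidths=1.0)
        axes[2].set_title("ground truth", fontsize=8)
    for ax in axes:
        ax.set_axis_off()
    fig.tight_layout()
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def save_solution_npz(path, solution) -> None:
    """NPZ bundle of one solution: mask, class probabilities, U-map, Upp."""
    np.savez_compressed(
        path,
        labels=solution.mask.labels,
        probs=solution.probs.astype(np.float32),
        umap=solution.umap.astype(np.float32),
        upp=np.float64(solution.upp),
        member_id=np.array(solution.member_id),
    )
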