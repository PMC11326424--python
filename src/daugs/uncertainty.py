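"""Uncertainty mapping and data-adaptive model selection.

With a small sliding-window stride, every pixel of a series is segmented
several times — once per covering space-time patch.  Ideally the network
assigns the same myocardium probability in each patch; disagreement signals
reduced confidence.  The *uncertainty map* (U-map) is the per-pixel
population standard deviation of those covering-patch myocardium
probabilities:

    U(x, y) = std{ p_i(x, y) : patch i covers (x, y) }

Since each p_i lies in [0, 1], the U-map lies in [0, 0.5]; the supremum is
attained exactly by a two-point {0, 1} coverage pattern.  The per-case
selection score is the mean per-pixel energy

    Upp = ||U||_F^2 / N_myo,

the sum of squared U-map values normalised by the number of predicted
myocardial pixels.  Data-adaptive selection runs *every* pool member on a
test case and keeps the solution with minimal Upp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import LabelMask, MYOCARDIUM, PerfusionSeries, as_labels
from .patches import PatchGrid, PatchProbabilityStack
from .phantom import inject_motion_error
from .pool import ModelPool, PoolMember, segment

__all__ = [
    "SegmentationSolution",
    "compute_umap",
    "compute_upp",
    "total_energy_metric",
    "daugs_select",
    "motion_error_sweep",
]

UMAP_MAX = 0.5  # analytic supremum of a std of values in [0, 1]


@dataclass
class SegmentationSolution:
    """One pool member's output for one series, with its uncertainty."""

    mask: LabelMask
    probs: np.ndarray  # H x W x 3 averaged class probabilities
    umap: np.ndarray  # H x W uncertainty map in [0, 0.5]
    upp: float
    member_id: str = ""

    @property
    def n_myo(self) -> int:
        return self.mask.n_pixels(MYOCARDIUM)


def compute_umap(stack: PatchProbabilityStack) -> np.ndarray:
    """Per-pixel population std of covering-patch myocardium probabilities.

    Pixels covered by a single patch get exactly 0.  Values are clipped to
    the analytic range [0, 0.5] (clipping only ever removes floating-point
    dust).
    """
    if stack.grid.n_patches == 0:
        raise ValueError("empty patch stack")
    s, _, n = stack.moment_maps()
    if n.min() < 1:
        raise ValueError("stack does not cover every pixel")
    mean = s / n
    # second (centred) pass, plus min/max tracking so pixels whose covering
    # probabilities agree exactly get an exact zero
    p = stack.grid.patch_size
    ss = np.zeros_like(mean)
    vmin = np.full_like(mean, np.inf)
    vmax = np.full_like(mean, -np.inf)
    for i, (r, c) in enumerate(stack.grid.origins):
        blk = stack.patch_myo[i]
        win = (slice(r, r + p), slice(c, c + p))
        d = blk - mean[win]
        ss[win] += d * d
        np.minimum(vmin[win], blk, out=vmin[win])
        np.maximum(vmax[win], blk, out=vmax[win])
    umap = np.clip(np.sqrt(ss / n), 0.0, UMAP_MAX)
    umap[vmax == vmin] = 0.0
    return umap


def compute_upp(umap: np.ndarray, mask: LabelMask | np.ndarray) -> float:
    """Mean per-pixel U-map energy: sum of squares over N_myo.

    The Frobenius sum runs over the whole cropped frame.  An empty
    myocardium prediction returns +inf: a solution that segments nothing is
    maximally distrusted rather than vacuously certain.
    """
    umap = np.asarray(umap, float)
    if umap.min() < 0:
        raise ValueError("umap contains negative values (upstream bug)")
    n_myo = int(np.count_nonzero(as_labels(mask) == MYOCARDIUM))
    if n_myo == 0:
        return float("inf")
    return float(np.sum(umap**2) / n_myo)


def total_energy_metric(umap: np.ndarray) -> float:
    """Total (unnormalised) U-map energy — the alternative selection score."""
    umap = np.asarray(umap, float)
    return float(np.sum(umap**2))


def _solve_one(member: PoolMember, series: PerfusionSeries,
               grid: PatchGrid) -> SegmentationSolution:
    probs, stack, mask = segment(member.model, series, grid)
    umap = compute_umap(stack)
    return SegmentationSolution(
        mask=mask, probs=probs, umap=umap,
        upp=compute_upp(umap, mask), member_id=member.member_id,
    )


def daugs_select(
    pool: ModelPool,
    series: PerfusionSeries,
    grid: PatchGrid,
    selection_metric: str = "upp",
    log: list | None = None,
) -> SegmentationSolution:
    """Run every pool member on the series; keep the least-uncertain result.

    Ties break by pool manifest order.  With ``selection_metric="upp"``
    (default) the score is the per-pixel energy; ``"total_energy"`` uses the
    unnormalised sum of squares.  If ``log`` is a list, one dict per member
    (member_id, upp, score) is appended for audit.
    """
    if selection_metric not in ("upp", "total_energy"):
        raise ValueError(f"unknown selection metric {selection_metric!r}")
    best: SegmentationSolution | None = None
    best_score = float("inf")
    any_nonempty = False
    for member in pool.members:
        sol = _solve_one(member, series, grid)
        score = (
            sol.upp if selection_metric == "upp"
            else total_energy_metric(sol.umap)
        )
        if sol.n_myo > 0:
            any_nonempty = True
        if log is not None:
            log.append(
                {"series_id": series.series_id, "member_id": member.member_id,
                 "upp": sol.upp, "score": score}
            )
        if best is None or score < best_score:
            best, best_score = sol, score
    if not any_nonempty:
        raise RuntimeError(
            f"all pool members produced empty myocardium on series "
            f"{series.series_id!r}"
        )
    return best


def motion_error_sweep(
    pool_or_member,
    phantom_set: list[tuple[PerfusionSeries, LabelMask]],
    shift_levels: list[float],
    seed: int,
    grid: PatchGrid | None = None,
):
    """Upp as a function of injected motion-correction error.

    For each shift level (in pixels; must include >= 2 levels, typically
    starting at 0 as the control condition), translates randomly chosen
    frames of each clean phantom, segments, and computes Upp.  Returns a
    tidy DataFrame of per-series rows plus the Spearman rank correlation of
    level vs per-level median Upp (positive = uncertainty tracks corruption).
    """
    import pandas as pd

    if len(shift_levels) < 2:
        raise ValueError("need at least 2 shift levels (including a control)")
    if isinstance(pool_or_member, ModelPool):
        members = pool_or_member.members
    else:
        members = [pool_or_member]
    if grid is None:
        raise ValueError("an inference grid must be provided")

    rng = np.random.default_rng(seed)
    rows = []
    for level in shift_levels:
        for series, mask in phantom_set:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            n_bad = max(1, series.n_frames // 5) if level > 0 else 0
            corrupted = inject_motion_error(series, mask, n_bad, level, sub_seed)
            for member in members:
                sol = _solve_one(member, corrupted, grid)
                rows.append(
                    {"level_px": level, "series_id": series.series_id,
                     "member_id": member.member_id, "upp": sol.upp}
                )
    table = pd.DataFrame(rows)
    medians = table.groupby("level_px")["upp"].median().reset_index()
    rho = float(stats.spearmanr(medians["level_px"], medians["upp"]).statistic)
    return table, medians, rho
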