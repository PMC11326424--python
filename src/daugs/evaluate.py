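"""Segmentation scoring, failure detection, and the two-regime comparison.

Metrics follow the conventions of the myocardial-segmentation literature:
pixelwise Dice coefficient per class, and the undirected 95th-percentile
Hausdorff distance (max of the two directed 95th-percentile boundary
distances, in millimetres).  A prediction counts as a *failed* segmentation
when (i) bloodpool is included inside the delineated myocardial contour
(outside the true cavity), or (ii) the myocardial contour is noncontiguous
— operationalised topologically as "not a single 8-connected ring enclosing
exactly one cavity".
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import BLOODPOOL, LABEL_CODES, MYOCARDIUM, as_labels

__all__ = ["dice", "hd95", "detect_failure", "compare_methods"]


def dice(pred, truth, class_code: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) for one class.

    Defined as 1.0 when both class sets are empty and 0.0 when exactly one
    is empty.
    """
    if class_code not in LABEL_CODES:
        raise ValueError(f"unknown class code {class_code}")
    a = as_labels(pred) == class_code
    b = as_labels(truth) == class_code
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of the class whose 4-neighbourhood leaves the class."""
    inner = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~inner


def hd95(pred, truth, class_code: int,
         spacing_mm: tuple[float, float] = (1.0, 1.0)) -> float:
    """Undirected 95th-percentile Hausdorff distance in millimetres.

    The directed distance from A to B is the 95th percentile of each
    boundary pixel of A's nearest-neighbour distance to the boundary of B;
    the undirected value is the maximum of the two directions.  Distances
    are computed in physical coordinates (pixel indices scaled by
    ``spacing_mm``).  If either class set is empty the result is +inf with
    a warning (counted as a failure downstream).
    """
    if class_code not in LABEL_CODES:
        raise ValueError(f"unknown class code {class_code}")
    a = as_labels(pred) == class_code
    b = as_labels(truth) == class_code
    if not a.any() or not b.any():
        warnings.warn(
            f"hd95: empty class-{class_code} set; returning inf", stacklevel=2
        )
        return float("inf")
    sy, sx = spacing_mm
    pa = np.argwhere(_boundary(a)) * np.array([sy, sx])
    pb = np.argwhere(_boundary(b)) * np.array([sy, sx])
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


_EIGHT = ndimage.generate_binary_structure(2, 2)
_FOUR = ndimage.generate_binary_structure(2, 1)


def detect_failure(pred, min_component_px: int = 5) -> tuple[bool, bool]:
    """Flag the two failed-segmentation criteria on a predicted mask.

    Returns ``(failure_bloodpool, failure_noncontiguous)``:

    * *bloodpool inclusion*: some bloodpool-labelled pixel lies inside the
      filled outer boundary of the myocardium but outside the single
      largest enclosed cavity (i.e. bloodpool trapped within the muscle
      band rather than in the LV cavity);
    * *noncontiguous contour*: after discarding myocardial components
      smaller than ``min_component_px``, the myocardium is not one single
      8-connected component enclosing exactly one cavity.  Pinholes smaller
      than ``min_component_px`` are ignored when counting cavities — the
      criterion targets contour-level defects a rater would see, not
      single-pixel dropouts.

    An all-background prediction raises both flags ("empty prediction").
    """
    labels = as_labels(pred)
    myo = labels == MYOCARDIUM
    # drop speckle components below the minimum size
    comp, n_comp = ndimage.label(myo, structure=_EIGHT)
    if n_comp:
        sizes = ndimage.sum_labels(myo, comp, index=np.arange(1, n_comp + 1))
        keep = np.flatnonzero(sizes >= min_component_px) + 1
        myo = np.isin(comp, keep)
        comp, n_comp = ndimage.label(myo, structure=_EIGHT)
    if not myo.any():
        warnings.warn("detect_failure: empty myocardium prediction", stacklevel=2)
        return True, True

    filled = ndimage.binary_fill_holes(myo)
    holes = filled & ~myo
    hole_comp, n_holes = ndimage.label(holes, structure=_FOUR)
    if n_holes:
        hole_sizes = ndimage.sum_labels(
            holes, hole_comp, index=np.arange(1, n_holes + 1)
        )
        cavity = hole_comp == (int(np.argmax(hole_sizes)) + 1)
        n_cavities = int(np.count_nonzero(hole_sizes >= min_component_px))
    else:
        cavity = np.zeros_like(myo)
        n_cavities = 0

    blood = labels == BLOODPOOL
    failure_bloodpool = bool((blood & holes & ~cavity).any())
    failure_noncontiguous = not (n_comp == 1 and n_cavities == 1)
    return failure_bloodpool, failure_noncontiguous


# ---------------------------------------------------------------------------
# DAUGS-vs-established comparison experiment
# ---------------------------------------------------------------------------

def _evaluate_solution(series, truth, sol, method: str) -> dict:
    d = dice(sol.mask, truth, MYOCARDIUM)
    h = hd95(sol.mask, truth, MYOCARDIUM, series.pixel_spacing_mm) \
        if (sol.mask.labels == MYOCARDIUM).any() and \
           (truth.labels == MYOCARDIUM).any() else float("inf")
    fb, fn = detect_failure(sol.mask)
    return {
        "series_id": series.series_id,
        "method": method,
        "member_id": sol.member_id,
        "dice_myo": d,
        "hd95_mm": h,
        "failure_bloodpool": fb,
        "failure_noncontiguous": fn,
        "failed": fb or fn,
        "upp": sol.upp,
    }


def compare_methods(pool, test_sets: dict, grid, out_dir=None):
    """Evaluate the data-adaptive and established regimes on test sets.

    Parameters
    ----------
    pool : ModelPool
    test_sets : dict mapping dataset name -> list of (series, mask) pairs
        e.g. ``{"internal": [...], "shifted": [...]}``.
    grid : PatchGrid
        Inference grid.
    out_dir : path-like, optional
        If given, per-series and summary CSVs are written there.

    Returns
    -------
    per_series : pandas.DataFrame
        One row per (dataset, series, method).
    summary : pandas.DataFrame
        Per (dataset, method): mean/sd Dice and HD95, failure rate, plus
        two-tailed comparison statistics per dataset (unpaired t-test on
        Dice, Fisher's exact test on failure counts).
    """
    import pandas as pd

    # local imports: this module is imported by pool/uncertainty for metrics
    from .pool import established_select, segment
    from .uncertainty import compute_umap, compute_upp, daugs_select, \
        SegmentationSolution

    best = established_select(pool)
    rows = []
    for name, pairs in test_sets.items():
        for series, truth in pairs:
            sol = daugs_select(pool, series, grid)
            rows.append(dict(dataset=name,
                             **_evaluate_solution(series, truth, sol, "daugs")))
            probs, stack, mask = segment(best.model, series, grid)
            umap = compute_umap(stack)
            est = SegmentationSolution(
                mask=mask, probs=probs, umap=umap,
                upp=compute_upp(umap, mask), member_id=best.member_id,
            )
            rows.append(dict(dataset=name,
                             **_evaluate_solution(series, truth, est,
                                                  "established")))
    per_series = pd.DataFrame(rows)

    summaries = []
    for name, grp in per_series.groupby("dataset"):
        d_daugs = grp.loc[grp.method == "daugs", "dice_myo"].to_numpy()
        d_est = grp.loc[grp.method == "established", "dice_myo"].to_numpy()
        f_daugs = grp.loc[grp.method == "daugs", "failed"].to_numpy()
        f_est = grp.loc[grp.method == "established", "failed"].to_numpy()
        if len(d_daugs) > 1 and (d_daugs.std() > 0 or d_est.std() > 0):
            p_dice = float(stats.ttest_ind(d_daugs, d_est).pvalue)
        else:
            p_dice = float("nan")
        table = [
            [int(f_daugs.sum()), int(len(f_daugs) - f_daugs.sum())],
            [int(f_est.sum()), int(len(f_est) - f_est.sum())],
        ]
        p_fail = float(stats.fisher_exact(table)[1])
        for method, dd, ff in (("daugs", d_daugs, f_daugs),
                               ("established", d_est, f_est)):
            sub = grp[grp.method == method]
            hd = sub["hd95_mm"].to_numpy()
            hd_finite = hd[np.isfinite(hd)]
            summaries.append({
                "dataset": name,
                "method": method,
                "n_series": len(dd),
                "dice_mean": float(dd.mean()),
                "dice_sd": float(dd.std(ddof=1)) if len(dd) > 1 else 0.0,
                "hd95_mean_mm": float(hd_finite.mean()) if len(hd_finite) else float("inf"),
                "hd95_sd_mm": float(hd_finite.std(ddof=1)) if len(hd_finite) > 1 else 0.0,
                "failure_rate": float(ff.mean()),
                "p_dice_ttest": p_dice,
                "p_failure_fisher": p_fail,
            })
    summary = pd.DataFrame(summaries)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_series.to_csv(out / "per_series.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
    return per_series, summary
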