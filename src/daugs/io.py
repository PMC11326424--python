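"""Reading and writing series/mask bundles.

Two on-disk representations per series:

* **NPZ bundle** — ``intensities`` (H x W x T), ``labels`` (H x W, optional)
  and metadata arrays in one ``.npz`` file;
* **NIfTI pair** — a 4D series volume plus a 3D mask volume (via nibabel),
  with a JSON sidecar carrying pixel spacing, frame times, heart centre and
  any generator config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import LabelMask, PerfusionSeries

__all__ = [
    "save_series_npz",
    "load_series_npz",
    "save_series_nifti",
    "load_series_nifti",
]


def _meta(series: PerfusionSeries, extra: dict | None) -> dict:
    meta = {
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "frame_times_s": [float(t) for t in series.frame_times_s],
        "heart_center": list(series.heart_center),
        "series_id": series.series_id,
    }
    if extra:
        meta["generator_config"] = extra
    return meta


def save_series_npz(path, series: PerfusionSeries, mask: LabelMask | None = None,
                    config: dict | None = None) -> None:
    path = Path(path)
    arrays = {
        "intensities": series.intensities.astype(np.float32),
        "meta_json": np.array(json.dumps(_meta(series, config))),
    }
    if mask is not None:
        arrays["labels"] = mask.labels
    np.savez_compressed(path, **arrays)


def load_series_npz(path) -> tuple[PerfusionSeries, LabelMask | None]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        series = PerfusionSeries(
            intensities=z["intensities"].astype(np.float64),
            pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
            frame_times_s=np.array(meta["frame_times_s"]),
            heart_center=tuple(meta["heart_center"]),
            series_id=meta["series_id"],
        )
        mask = LabelMask(z["labels"]) if "labels" in z else None
    return series, mask


def save_series_nifti(prefix, series: PerfusionSeries,
                      mask: LabelMask | None = None,
                      config: dict | None = None) -> None:
    """Write ``<prefix>.nii.gz`` (+ ``<prefix>_mask.nii.gz``, sidecar JSON)."""
    import nibabel as nib

    prefix = Path(prefix)
    dy, dx = series.pixel_spacing_mm
    affine = np.diag([dy, dx, 1.0, 1.0])
    vol4 = series.intensities[:, :, None, :].astype(np.float32)  # H,W,1,T
    nib.save(nib.Nifti1Image(vol4, affine), str(prefix) + ".nii.gz")
    if mask is not None:
        nib.save(
            nib.Nifti1Image(mask.labels[:, :, None].astype(np.int16), affine),
            str(prefix) + "_mask.nii.gz",
        )
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(_meta(series, config), fh, indent=2)


def load_series_nifti(prefix) -> tuple[PerfusionSeries, LabelMask | None]:
    import nibabel as nib

    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    vol = np.asarray(nib.load(prefix + ".nii.gz").dataobj, dtype=np.float64)
    series = PerfusionSeries(
        intensities=vol[:, :, 0, :],
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        frame_times_s=np.array(meta["frame_times_s"]),
        heart_center=tuple(meta["heart_center"]),
        series_id=meta["series_id"],
    )
    mask = None
    mask_path = Path(prefix + "_mask.nii.gz")
    if mask_path.exists():
        mask = LabelMask(np.asarray(nib.load(mask_path).dataobj,
                                    dtype=np.int16)[:, :, 0])
    return series, mask
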