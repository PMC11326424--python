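"""Training-time data augmentation.

Two families:

* *segmentation-variant*: one random affine transform (rotation, shear,
  translation, scale) applied identically to every frame and to the ground
  truth mask, so the contours move with the image;
* *segmentation-invariant*: intensity-only perturbations — additive Gaussian
  noise, gamma-style contrast change, and a smooth multiplicative bias field
  (constant across time) emulating coil-sensitivity weighting — which leave
  the ground truth untouched.

Both are driven by an explicit numpy Generator so training streams are
reproducible per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LabelMask, PerfusionSeries

__all__ = ["AugmentPolicy", "apply_affine", "augment_variant",
           "augment_invariant"]


@dataclass(frozen=True)
class AugmentPolicy:
    """Ranges and per-transform application probabilities.

    Defaults are label-preserving at the 128-pixel analysis scale: rotation
    within ±15°, shear ±8°, translation ±8 px, scale 0.9–1.1, gamma 0.7–1.4,
    noise sigma up to 0.05 (on the [0, 1] intensity scale), bias-field
    amplitude up to ±30%.
    """

    rotation_deg: float = 15.0
    shear_deg: float = 8.0
    translation_px: float = 8.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma_range: tuple[float, float] = (0.0, 0.05)
    contrast_gamma_range: tuple[float, float] = (0.7, 1.4)
    modulation_n_bumps: int = 3
    modulation_amplitude_range: tuple[float, float] = (0.0, 0.3)
    modulation_width_range: tuple[float, float] = (0.3, 0.8)
    p_affine: float = 1.0
    p_noise: float = 0.5
    p_contrast: float = 0.5
    p_modulation: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0.5 < lo <= hi < 2.0):
            raise ValueError(f"scale_range must lie within (0.5, 2.0), got {self.scale_range}")
        for name in ("p_affine", "p_noise", "p_contrast", "p_modulation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


IDENTITY_POLICY = AugmentPolicy(
    rotation_deg=0, shear_deg=0, translation_px=0, scale_range=(1.0, 1.0),
    noise_sigma_range=(0.0, 0.0), contrast_gamma_range=(1.0, 1.0),
    modulation_amplitude_range=(0.0, 0.0), p_affine=0, p_noise=0,
    p_contrast=0, p_modulation=0,
)


def _sample_affine(policy: AugmentPolicy, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """2x2 matrix + translation of a random rotation/shear/scale/shift."""
    while True:
        rot = math.radians(rng.uniform(-policy.rotation_deg, policy.rotation_deg))
        shear = math.radians(rng.uniform(-policy.shear_deg, policy.shear_deg))
        scale = rng.uniform(*policy.scale_range)
        ty, tx = rng.uniform(-policy.translation_px, policy.translation_px, size=2)
        R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        S = np.array([[1.0, math.tan(shear)], [0.0, 1.0]])
        M = scale * R @ S
        if abs(np.linalg.det(M)) > 1e-3:  # degenerate transforms are resampled
            return M, np.array([ty, tx])


def apply_affine(
    series: PerfusionSeries,
    mask: LabelMask,
    M: np.ndarray,
    t: np.ndarray,
) -> tuple[PerfusionSeries, LabelMask]:
    """Apply one affine map (about the image centre) to image and mask alike.

    ``M`` is the 2x2 linear part in (row, col) coordinates, ``t`` the
    translation in pixels.  Every frame and the mask get the identical
    geometric map; out-of-frame regions fill with background (intensity 0,
    label 0); labels use nearest-neighbour resampling.
    """
    h, w = series.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # affine_transform maps output coords -> input coords: inverse map.
    Minv = np.linalg.inv(M)
    offset = center - Minv @ (center + t)
    vol = np.stack(
        [
            ndimage.affine_transform(
                series.intensities[:, :, f], Minv, offset=offset, order=1,
                mode="constant", cval=0.0,
            )
            for f in range(series.n_frames)
        ],
        axis=2,
    )
    lab = ndimage.affine_transform(
        mask.labels, Minv, offset=offset, order=0, mode="constant", cval=0
    )
    return series.with_intensities(vol), LabelMask(lab)


def augment_variant(
    series: PerfusionSeries,
    mask: LabelMask,
    policy: AugmentPolicy,
    rng: np.random.Generator,
) -> tuple[PerfusionSeries, LabelMask]:
    """Sample one random affine transform and apply it to image and mask."""
    if rng.uniform() >= policy.p_affine:
        return series, mask
    M, t = _sample_affine(policy, rng)
    return apply_affine(series, mask, M, t)


def augment_invariant(
    series: PerfusionSeries,
    policy: AugmentPolicy,
    rng: np.random.Generator,
) -> PerfusionSeries:
    """Intensity-only perturbations; ground truth is untouched by contract."""
    vol = series.intensities.copy()
    h, w = series.shape[:2]

    if rng.uniform() < policy.p_contrast:
        gamma = rng.uniform(*policy.contrast_gamma_range)
        vol = np.clip(vol, 0.0, None) ** gamma

    if rng.uniform() < policy.p_modulation:
        amp = rng.uniform(*policy.modulation_amplitude_range)
        if amp > 0:
            rr, cc = np.mgrid[0:h, 0:w].astype(float)
            fld = np.zeros((h, w))
            for _ in range(policy.modulation_n_bumps):
                r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
                width = rng.uniform(*policy.modulation_width_range) * max(h, w)
                fld += rng.choice([-1.0, 1.0]) * np.exp(
                    -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2)
                )
            m = np.abs(fld).max()
            if m > 0:
                vol = vol * (1.0 + amp * fld[:, :, None] / m)

    if rng.uniform() < policy.p_noise:
        sigma = rng.uniform(*policy.noise_sigma_range)
        if sigma > 0:
            vol = vol + rng.normal(0.0, sigma, size=vol.shape)

    return series.with_intensities(np.clip(vol, 0.0, 1.0))
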