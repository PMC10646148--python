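"""Nuclei and neurite mask construction.

The segmentation mirrors the semi-automated confocal workflow it reimplements:

* **Nuclei/soma mask** (from the DAPI channel): Huang threshold → delete
  small components (equivalent-circle radius below a cutoff) → dilate by a
  few pixels to take in the thin cytoplasmic rim of a mature motor neuron.
* **Neurite mask** (from the Map2 channel): the channel is duplicated; one
  copy yields a *high-intensity mask* (contrast enhancement → Gaussian blur
  → moment-preserving threshold) covering somata, axon hillocks and bright
  neurite cores, the other a *LoG mask* (contrast enhancement → inverted
  Laplacian-of-Gaussian → moment-preserving threshold) recovering thin faint
  segments. The final neurite mask is their union minus the soma mask.

Sigmas are specified in micrometers and converted with the image calibration,
so the filters behave identically across magnifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .image import BinaryMask, CalibrationError, Image2D
from .thresholds import (
    DegenerateHistogramError,
    apply_threshold,
    threshold_huang,
    threshold_moments,
)

logger = logging.getLogger(__name__)


@dataclass
class MaskingParams:
    """Tunable parameters of the segmentation stage.

    Defaults follow the published workflow: 0.1% saturated pixels for
    contrast enhancement, 2 µm Gaussian blur, components under 20 px
    equivalent radius removed, nuclei expanded by 5 px. The LoG scale has no
    published value; it defaults to the blur sigma (2 µm) and should be set
    deliberately (see package docs).
    """

    saturated_fraction: float = 0.001
    blur_sigma_um: float = 2.0
    log_sigma_um: float = 2.0
    min_outlier_radius_px: float = 20.0
    nuclei_expand_px: float = 5.0
    nuclei_threshold_method: str = "huang"
    intensity_threshold_method: str = "moments"
    small_object_mode: str = "component"  # or "median" (raster despeckle)

    def __post_init__(self) -> None:
        if not 0 <= self.saturated_fraction < 1:
            raise ValueError("saturated_fraction must lie in [0, 1)")
        if self.blur_sigma_um <= 0 or self.log_sigma_um <= 0:
            raise ValueError("filter sigmas must be positive")
        if self.min_outlier_radius_px < 0 or self.nuclei_expand_px < 0:
            raise ValueError("radii must be non-negative")


class NucleiMasks(NamedTuple):
    """Pre-expansion nuclei mask (for counting) and expanded soma mask."""

    nuclei: BinaryMask
    soma: BinaryMask


def _dtype_max(dtype: np.dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 1.0


def enhance_contrast(img: Image2D, saturated_fraction: float = 0.001) -> Image2D:
    """Linear contrast stretch saturating a stated fraction of pixels.

    Clip bounds are the order statistics at ``saturated_fraction / 2`` from
    each tail (symmetric allocation); the clipped image is rescaled linearly
    to the full dtype range (or [0, 1] for float input). Order-preserving on
    non-clipped pixels. A constant image is returned unchanged.
    """
    if not 0 <= saturated_fraction < 1:
        raise ValueError("saturated_fraction must lie in [0, 1)")
    a = np.asarray(img.values)
    flat = np.sort(a, axis=None)
    n = flat.size
    k = int(round(n * saturated_fraction / 2.0))
    k = min(k, (n - 1) // 2)
    lo = float(flat[k])
    hi = float(flat[n - 1 - k])
    if hi == lo:
        logger.info("enhance_contrast: constant clip range; image returned unchanged")
        return img.with_values(a.copy())
    top = _dtype_max(a.dtype)
    out = (a.astype(np.float64) - lo) / (hi - lo) * top
    out = np.clip(out, 0.0, top)
    if np.issubdtype(a.dtype, np.integer):
        out = np.rint(out).astype(a.dtype)
    return img.with_values(out)


def gaussian_blur(img: Image2D, sigma_um: float) -> Image2D:
    """Normalized Gaussian smoothing with sigma given in micrometers.

    ``sigma_px = sigma_um / pixel_size_um``; reflective boundaries keep the
    mean intensity essentially unchanged. Returns a float-valued image.
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    sigma_px = sigma_um / img.pixel_size_um
    out = ndi.gaussian_filter(np.asarray(img.values, dtype=np.float64), sigma_px, mode="reflect")
    return img.with_values(out)


def log_filter(img: Image2D, sigma_um: float) -> Image2D:
    """Inverted Laplacian-of-Gaussian response at scale ``sigma_um``.

    The raw Laplacian is negated so thin bright ridges (neurites on dark
    background) produce *positive* responses; a constant image maps to zero.
    Returns the real-valued response; rescale to a dtype range before
    histogram thresholding (see :func:`rescale_to_dtype`).
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    sigma_px = sigma_um / img.pixel_size_um
    a = np.asarray(img.values, dtype=np.float64)
    raw = ndi.gaussian_laplace(a, sigma_px, mode="reflect")
    # the truncated discrete kernel leaks a small DC term; remove it so a
    # constant image maps to an exactly zero response
    dc = float(ndi.gaussian_laplace(np.ones((1, 1)), sigma_px, mode="reflect")[0, 0])
    resp = -(raw - dc * a)
    return img.with_values(resp)


def rescale_to_dtype(values: np.ndarray, dtype: np.dtype) -> np.ndarray:
    """Map a real-valued response linearly onto [0, dtype max] and round."""
    a = np.asarray(values, dtype=np.float64)
    lo, hi = float(a.min()), float(a.max())
    top = _dtype_max(np.dtype(dtype))
    if hi == lo:
        out = np.zeros_like(a)
    else:
        out = (a - lo) / (hi - lo) * top
    if np.issubdtype(np.dtype(dtype), np.integer):
        return np.rint(out).astype(dtype)
    return out


def remove_small_components(mask: BinaryMask, min_radius_px: float) -> BinaryMask:
    """Delete 8-connected components with equivalent-circle radius below cutoff.

    A component of area A has equivalent radius sqrt(A / pi); components with
    radius strictly below ``min_radius_px`` are removed, all others untouched.
    """
    if min_radius_px < 0:
        raise ValueError("min_radius_px must be non-negative")
    if min_radius_px == 0:
        return mask.with_values(mask.values)
    labels, n = measure.label(mask.values, connectivity=2, return_num=True)
    if n == 0:
        return mask.with_values(mask.values)
    areas = np.bincount(labels.ravel())[1:]
    min_area = np.pi * min_radius_px**2
    keep = np.flatnonzero(areas >= min_area) + 1
    out = np.isin(labels, keep)
    return mask.with_values(out)


def despeckle_median(img: Image2D, radius_px: int = 2) -> Image2D:
    """ImageJ-style remove-outliers alternative: median filter despeckling."""
    size = 2 * int(radius_px) + 1
    return img.with_values(ndi.median_filter(np.asarray(img.values), size=size))


def expand_mask(mask: BinaryMask, by_px: float) -> BinaryMask:
    """Dilate by a Euclidean-distance criterion (disk structuring element).

    Output pixels are those whose center lies within ``by_px`` of any input
    pixel center; ``by_px = 0`` is the identity. Monotone in the input mask.
    """
    if by_px < 0:
        raise ValueError("by_px must be non-negative")
    if by_px == 0 or not mask.values.any():
        return mask.with_values(mask.values)
    dist = ndi.distance_transform_edt(~mask.values)
    return mask.with_values(dist <= by_px)


def build_nuclei_mask(dapi: Image2D, params: MaskingParams | None = None) -> NucleiMasks:
    """DAPI → (nuclei mask, expanded soma mask).

    Huang threshold, small-component removal, then distance-based expansion.
    The pre-expansion mask is kept separately: soma counting must use it,
    because expansion can fuse adjacent cells.
    """
    params = params or MaskingParams()
    t = threshold_huang(dapi)
    raw = BinaryMask(apply_threshold(dapi, t), dapi.pixel_size_um)
    if params.small_object_mode == "median":
        med = despeckle_median(
            dapi.with_values(raw.values.astype(np.uint8)),
            radius_px=int(params.min_outlier_radius_px),
        )
        nuclei = raw.with_values(med.values > 0)
    else:
        nuclei = remove_small_components(raw, params.min_outlier_radius_px)
    soma = expand_mask(nuclei, params.nuclei_expand_px)
    return NucleiMasks(nuclei=nuclei, soma=soma)


def build_neurite_mask(
    map2: Image2D, soma_mask: BinaryMask, params: MaskingParams | None = None
) -> BinaryMask:
    """Map2 + soma mask → final neurite mask.

    Two independently contrast-enhanced copies produce the high-intensity
    mask and the LoG mask; the neurite mask is their union with the soma
    mask subtracted, hence always disjoint from it. A blank (constant) Map2
    channel yields an empty mask rather than an error.
    """
    params = params or MaskingParams()
    if map2.shape != soma_mask.shape:
        raise CalibrationError(
            f"map2 {map2.shape} and soma mask {soma_mask.shape} shapes differ"
        )
    dtype = np.asarray(map2.values).dtype

    # Both branches threshold the real-valued filter responses directly
    # (the histogram methods accept arbitrary value grids); re-quantizing to
    # the integer dtype would dither the faint mask boundaries into
    # stair-step contours that skeletonize into spurious short branches.
    def _branch_high() -> np.ndarray:
        enhanced = enhance_contrast(map2, params.saturated_fraction)
        blurred = gaussian_blur(enhanced, params.blur_sigma_um)
        t = threshold_moments(blurred)
        return apply_threshold(blurred, t)

    def _branch_log() -> np.ndarray:
        enhanced = enhance_contrast(map2, params.saturated_fraction)
        resp = log_filter(enhanced, params.log_sigma_um)
        scaled = map2.with_values(
            rescale_to_dtype(resp.values, np.dtype(np.float64)) * _dtype_max(dtype)
        )
        t = threshold_moments(scaled)
        return apply_threshold(scaled, t)

    union = np.zeros(map2.shape, dtype=bool)
    degenerate = 0
    for branch in (_branch_high, _branch_log):
        try:
            union |= branch()
        except DegenerateHistogramError:
            degenerate += 1
    if degenerate:
        logger.info(
            "build_neurite_mask: %d branch(es) degenerate (blank channel); "
            "contributing empty mask",
            degenerate,
        )
    final = union & ~soma_mask.values
    return BinaryMask(final, map2.pixel_size_um)
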