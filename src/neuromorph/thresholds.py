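"""Automatic histogram thresholding.

Two classical methods drive the segmentation pipeline:

* **Huang fuzziness threshold** — choose the graylevel minimizing the image's
  fuzziness, measured as the Shannon entropy of a membership function that
  assigns each gray value a membership in its class based on distance to the
  class mean (Huang & Wang's formulation). Used for the nuclei mask.
* **Moment-preserving (Tsai) threshold** — choose the binarization whose
  two-level image preserves the first three graylevel moments of the input
  histogram. Used for both neurite masks.

Both are pure functions of the gray-level histogram: thresholds are computed
on the distinct observed values with their multiplicities (equivalent to the
native 256- or 65,536-bin histogram, since empty bins contribute nothing),
so shuffling pixel positions never changes the result.

Foreground convention, fixed package-wide: a pixel is foreground iff its
value is **strictly above** the returned threshold; ties go to background.
"""

from __future__ import annotations

import numpy as np

from .image import Image2D

__all__ = [
    "DegenerateHistogramError",
    "threshold_huang",
    "threshold_moments",
    "threshold_isodata",
    "apply_threshold",
]


class DegenerateHistogramError(ValueError):
    """Raised when an image has fewer than two distinct gray values."""


def _as_array(img) -> np.ndarray:
    if isinstance(img, Image2D):
        return np.asarray(img.values)
    return np.asarray(img)


def _distinct(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v, c = np.unique(values.ravel(), return_counts=True)
    if v.size < 2:
        raise DegenerateHistogramError(
            f"histogram is degenerate: {v.size} distinct gray value(s); "
            "automatic thresholding requires at least two"
        )
    return v.astype(np.float64), c.astype(np.float64)


def _shannon(u: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy S(u) = -u ln u - (1-u) ln(1-u), with S(0)=S(1)=0."""
    u = np.clip(u, 0.0, 1.0)
    out = np.zeros_like(u)
    inner = (u > 0.0) & (u < 1.0)
    ui = u[inner]
    out[inner] = -ui * np.log(ui) - (1.0 - ui) * np.log1p(-ui)
    return out


def threshold_huang(img) -> float:
    """Huang & Wang's minimum-fuzziness threshold.

    For each candidate split of the histogram into background (values <= t)
    and foreground (values > t), each gray value g receives a membership
    u(g) = 1 / (1 + |g - mu_class| / C) in its own class, where mu_class is
    the class mean and C the gray-value range. The fuzziness of the split is
    the histogram-weighted Shannon entropy of these memberships; the split
    minimizing it wins. The returned threshold is the largest gray value of
    the optimal background class, so ``pixel > t`` selects the foreground.
    """
    v, c = _distinct(_as_array(img))
    K = v.size
    C = v[-1] - v[0]
    w = np.cumsum(c)                # background pixel count per split
    s = np.cumsum(c * v)            # background intensity sum per split
    total_w, total_s = w[-1], s[-1]
    mu0 = s[:-1] / w[:-1]                                # split i: bg = v[0..i]
    mu1 = (total_s - s[:-1]) / (total_w - w[:-1])        # fg = v[i+1..]
    n_splits = K - 1

    def scan(split_idx: np.ndarray, dtype) -> np.ndarray:
        """Fuzziness of the given splits, row-chunked to bound memory."""
        vv = v.astype(dtype)
        cc = c.astype(dtype)
        out = np.empty(split_idx.size, dtype=dtype)
        chunk = max(1, int(4_000_000 // K))
        idx = np.arange(K)
        for start in range(0, split_idx.size, chunk):
            rows = split_idx[start : start + chunk]
            mu = np.where(
                idx[None, :] <= rows[:, None],
                mu0[rows, None].astype(dtype),
                mu1[rows, None].astype(dtype),
            )
            u = 1.0 / (1.0 + np.abs(vv[None, :] - mu) / dtype(C))
            out[start : start + chunk] = _shannon(u) @ cc
        return out

    all_splits = np.arange(n_splits)
    if n_splits <= 512:
        fuzz = scan(all_splits, np.float64)
        best = int(all_splits[np.argmin(fuzz)])
    else:
        # two-stage exact scan: float32 screening of every split, then exact
        # float64 evaluation of the best candidates (float32 rounding is
        # orders of magnitude below the fuzziness gaps this span covers)
        rough = scan(all_splits, np.float32)
        top = all_splits[np.argsort(rough)[:256]]
        exact = scan(top, np.float64)
        best = int(top[np.argmin(exact)])
    return float(v[best])


def threshold_moments(img) -> float:
    """Tsai's moment-preserving threshold.

    Solves for the two representative levels z0 < z1 and the background
    fraction p0 such that a two-level image with a fraction p0 of pixels at
    z0 preserves the first three graylevel moments of the input, then places
    the threshold at the gray value whose cumulative histogram fraction is
    closest to p0 (ties broken toward the lower value).
    """
    v, c = _distinct(_as_array(img))
    p = c / c.sum()
    m1 = float(np.sum(p * v))
    m2 = float(np.sum(p * v**2))
    m3 = float(np.sum(p * v**3))

    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("zero gray-level variance; moments undefined")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise DegenerateHistogramError("coincident representative levels")
    p0 = (z1 - m1) / (z1 - z0)

    cum = np.cumsum(p)
    # Candidate thresholds are the distinct values except the maximum (a
    # threshold must split); below-threshold fraction for v[i] is cum[i]
    # under the strictly-above-foreground convention.
    best = int(np.argmin(np.abs(cum[:-1] - p0)))
    return float(v[best])


def threshold_isodata(img) -> float:
    """IsoData-style iterative intermeans threshold (the stock "default").

    Iterates t <- (mean below-or-equal t + mean above t) / 2 until stable;
    returned on the distinct-value grid so the strictly-above convention
    applies cleanly.
    """
    v, c = _distinct(_as_array(img))
    w = np.cumsum(c)
    s = np.cumsum(c * v)
    total_w, total_s = w[-1], s[-1]
    mu0 = s[:-1] / w[:-1]
    mu1 = (total_s - s[:-1]) / (total_w - w[:-1])
    mid = 0.5 * (mu0 + mu1)
    # Fixed point: the split i whose midpoint falls between v[i] and v[i+1].
    ok = (mid >= v[:-1]) & (mid < v[1:])
    if np.any(ok):
        best = int(np.flatnonzero(ok)[0])
    else:  # fall back to the split minimizing |mid - boundary|
        best = int(np.argmin(np.abs(mid - 0.5 * (v[:-1] + v[1:]))))
    return float(v[best])


_METHODS = {
    "huang": threshold_huang,
    "moments": threshold_moments,
    "isodata": threshold_isodata,
    "default-isodata": threshold_isodata,
}


def threshold_by_name(img, method: str) -> float:
    try:
        fn = _METHODS[method.lower()]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; choose from {sorted(_METHODS)}"
        ) from None
    return fn(img)


def apply_threshold(img, threshold: float) -> np.ndarray:
    """Boolean foreground under the strictly-above convention."""
    return _as_array(img) > threshold
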