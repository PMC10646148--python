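"""Calibrated raster containers and basic stack operations.

All images in the pipeline carry their spatial calibration (micrometers per
pixel) alongside the pixel grid, so that downstream length measurements are
reported in physical units regardless of acquisition settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Raised when images that must share shape/calibration do not."""


@dataclass
class Image2D:
    """A single-plane grayscale image with physical pixel size.

    Parameters
    ----------
    values : ndarray
        2-D array of non-negative intensities. Integer (8/16-bit) for raw
        acquisitions; floating point after linear filtering.
    pixel_size_um : float
        Micrometers per pixel (isotropic).
    """

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D array, got ndim={self.values.ndim}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "Image2D":
        """A new image with the same calibration and different pixel data."""
        return Image2D(np.asarray(values), self.pixel_size_um)


@dataclass
class BinaryMask:
    """A boolean raster aligned to a source :class:`Image2D`."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError(f"BinaryMask requires a 2-D array, got ndim={self.values.ndim}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(values, dtype=bool), self.pixel_size_um)


@dataclass
class Acquisition:
    """A two-channel acquisition: nuclear stain (DAPI) + neurite marker (Map2).

    ``dapi_stack``/``map2_stack`` optionally hold z-stacks; when present the
    measurement pipeline collapses them by maximum-intensity projection first.
    """

    dapi: Image2D
    map2: Image2D
    pixel_size_um: float
    dapi_stack: list[Image2D] | None = None
    map2_stack: list[Image2D] | None = None
    image_id: str = ""
    group: str = ""
    replicate: int = 0
    provenance: object = None

    def __post_init__(self) -> None:
        if self.dapi.shape != self.map2.shape:
            raise CalibrationError(
                f"channel shapes differ: dapi {self.dapi.shape} vs map2 {self.map2.shape}"
            )
        if not np.isclose(self.dapi.pixel_size_um, self.map2.pixel_size_um):
            raise CalibrationError("channel calibrations differ")


@dataclass
class MorphometryRecord:
    """Per-acquisition skeleton morphometry (the boxplot readouts).

    ``avg_branch_length_um`` is reported as 0 with ``avg_length_defined=False``
    when the image contains no branches, keeping tabular output rectangular.
    """

    image_id: str = ""
    group: str = ""
    replicate: int = 0
    n_somata: int = 0
    n_branches: int = 0
    n_junctions: int = 0
    n_endpoints: int = 0
    total_branch_length_um: float = 0.0
    avg_branch_length_um: float = 0.0
    avg_length_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "group": self.group,
            "replicate": self.replicate,
            "n_somata": self.n_somata,
            "n_branches": self.n_branches,
            "n_junctions": self.n_junctions,
            "n_endpoints": self.n_endpoints,
            "total_branch_length_um": self.total_branch_length_um,
            "avg_branch_length_um": self.avg_branch_length_um,
            "avg_length_defined": self.avg_length_defined,
        }


METRIC_COLUMNS = [
    "n_somata",
    "n_branches",
    "n_junctions",
    "n_endpoints",
    "total_branch_length_um",
    "avg_branch_length_um",
]


def max_project(stack: Sequence[Image2D]) -> Image2D:
    """Maximum-intensity projection of a z-stack.

    Each output pixel is the maximum of that pixel across all planes; this is
    the standard collapse of 3-D confocal data to a single analysis plane.
    """
    if len(stack) == 0:
        raise ValueError("max_project requires a non-empty stack")
    first = stack[0]
    for plane in stack[1:]:
        if plane.shape != first.shape:
            raise CalibrationError(
                f"stack plane shapes differ: {plane.shape} vs {first.shape}"
            )
        if not np.isclose(plane.pixel_size_um, first.pixel_size_um):
            raise CalibrationError("stack plane calibrations differ")
    out = np.maximum.reduce([p.values for p in stack])
    return Image2D(out, first.pixel_size_um)


def save_image(img: Image2D, path: str | Path) -> None:
    """Write a single-channel TIFF with resolution metadata (pixels/µm)."""
    res = 1.0 / img.pixel_size_um
    tifffile.imwrite(
        str(path),
        img.values,
        resolution=(res, res),
        metadata={"unit": "um", "pixel_size_um": img.pixel_size_um},
    )


def load_image(path: str | Path, pixel_size_um: float | None = None) -> Image2D:
    """Read a single-channel TIFF; pixel size from metadata unless given."""
    with tifffile.TiffFile(str(path)) as tf:
        values = tf.asarray()
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tiff(tf)
    if pixel_size_um is None:
        raise CalibrationError(
            f"{path}: no resolution metadata; pass pixel_size_um explicitly"
        )
    if values.ndim == 3:  # z-stack stored as pages
        planes = [Image2D(v, pixel_size_um) for v in values]
        return max_project(planes)
    return Image2D(values, pixel_size_um)


def _pixel_size_from_tiff(tf: "tifffile.TiffFile") -> float | None:
    page = tf.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    return den / num  # resolution stored as pixels per micrometer
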