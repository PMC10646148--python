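"""Per-cell immunofluorescence scoring.

Cells are defined by nucleus-derived regions (a single cell universe, so the
double-positive percentage has an unambiguous denominator). Marker channels
(e.g., CHAT and ISLET1 in maturing motor neurons) are binarized with an
automatic histogram threshold; a cell counts as positive for a marker when
at least a configurable fraction (default 50%) of its region pixels are
foreground. The per-cell positivity criterion is a package convention, not a
published rule, and is exposed in :class:`ScoringParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .image import Image2D
from .thresholds import apply_threshold, threshold_by_name, threshold_huang


@dataclass
class ScoringParams:
    auto_threshold_method: str = "isodata"   # marker binarization; huang/moments selectable
    min_particle_area_px: int = 64
    positive_fraction: float = 0.5
    n_cells_per_group: int = 60
    n_groups: int = 3

    def __post_init__(self) -> None:
        if self.min_particle_area_px < 0:
            raise ValueError("min_particle_area_px must be non-negative")
        if not 0 < self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in (0, 1]")
        if self.n_cells_per_group < 1 or self.n_groups < 1:
            raise ValueError("sampling counts must be >= 1")


@dataclass
class CellRecord:
    cell_id: int
    centroid: tuple[float, float]          # (row, col)
    area_px: int
    mean_intensity: dict[str, float] = field(default_factory=dict)
    positive: dict[str, bool] = field(default_factory=dict)


@dataclass
class CellTable:
    """Segmented cell regions: label raster plus per-cell records."""

    label_image: np.ndarray
    records: list[CellRecord]
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.records)


def segment_cells(nuclei: Image2D, params: ScoringParams | None = None) -> CellTable:
    """Nucleus-based cell regions: Huang threshold + small-particle removal.

    Returns an empty table (no error) for a blank nuclear channel.
    """
    params = params or ScoringParams()
    try:
        t = threshold_huang(nuclei)
    except Exception:
        return CellTable(
            np.zeros(nuclei.shape, dtype=np.int32), [], nuclei.pixel_size_um
        )
    fg = apply_threshold(nuclei, t)
    labels, n = measure.label(fg, connectivity=2, return_num=True)
    if n:
        areas = np.bincount(labels.ravel())[1:]
        small = np.flatnonzero(areas < params.min_particle_area_px) + 1
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels, n = measure.label(labels > 0, connectivity=2, return_num=True)
    records = []
    for rp in measure.regionprops(labels):
        records.append(
            CellRecord(
                cell_id=int(rp.label),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=int(rp.area),
            )
        )
    return CellTable(labels, records, nuclei.pixel_size_um)


def measure_intensity(cells: CellTable, channel: Image2D, name: str) -> CellTable:
    """Mean channel intensity over each cell region, stored under ``name``."""
    if not cells.records:
        return cells
    ids = [r.cell_id for r in cells.records]
    means = ndi.mean(np.asarray(channel.values, dtype=np.float64),
                     labels=cells.label_image, index=ids)
    for rec, m in zip(cells.records, np.atleast_1d(means)):
        rec.mean_intensity[name] = float(m)
    return cells


def _positivity(cells: CellTable, channel: Image2D, name: str,
                params: ScoringParams) -> None:
    t = threshold_by_name(channel, params.auto_threshold_method)
    fg = apply_threshold(channel, t).astype(np.float64)
    ids = [r.cell_id for r in cells.records]
    covered = np.atleast_1d(ndi.mean(fg, labels=cells.label_image, index=ids))
    for rec, frac in zip(cells.records, covered):
        rec.positive[name] = bool(frac >= params.positive_fraction)


@dataclass
class DoublePositiveResult:
    fraction: float
    n_cells: int
    n_double_positive: int
    group_fractions: list[float] | None = None


def classify_double_positive(
    cells: CellTable,
    chat: Image2D,
    islet1: Image2D,
    params: ScoringParams | None = None,
    subsample_seed: int | None = None,
) -> DoublePositiveResult:
    """Fraction of cells foreground-positive in both marker channels.

    With ``subsample_seed`` set, additionally reports per-group fractions
    over ``n_groups`` independent random samples of ``n_cells_per_group``
    cells (without replacement within a group), mimicking subsampled manual
    counting.
    """
    params = params or ScoringParams()
    if not cells.records:
        return DoublePositiveResult(0.0, 0, 0)
    _positivity(cells, chat, "chat", params)
    _positivity(cells, islet1, "islet1", params)
    flags = np.array(
        [r.positive["chat"] and r.positive["islet1"] for r in cells.records]
    )
    frac = float(flags.mean())
    groups = None
    if subsample_seed is not None:
        if params.n_cells_per_group > len(flags):
            raise ValueError(
                f"cannot sample {params.n_cells_per_group} cells from {len(flags)}"
            )
        rng = np.random.default_rng(subsample_seed)
        groups = [
            float(flags[rng.choice(len(flags), params.n_cells_per_group,
                                   replace=False)].mean())
            for _ in range(params.n_groups)
        ]
    return DoublePositiveResult(frac, int(flags.size), int(flags.sum()), groups)


def cells_to_rows(cells: CellTable) -> list[dict]:
    rows = []
    for r in cells.records:
        row = {
            "cell_id": r.cell_id,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "area_px": r.area_px,
        }
        for k, v in r.mean_intensity.items():
            row[f"mean_{k}"] = v
        for k, v in r.positive.items():
            row[f"positive_{k}"] = v
        rows.append(row)
    return rows
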