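"""Synthetic two-channel fluorescence acquisitions with known ground truth.

The generator emulates confocal fields of cultured spinal motor neurons:
round DAPI-bright nuclei, and Map2-labeled neurite trees grown by stochastic
segment elongation — each tip extends by an exponentially distributed segment
with small angular jitter and bifurcates with a fixed probability per step,
stopping at the field edge or a depth cap. Somata appear in the Map2 channel
brighter than neurites, neurites are rendered as ridge profiles 1-5 px wide
with Gaussian intensity falloff, and shot (Poisson) plus read (Gaussian)
noise is applied last.

Every acquisition is paired with a :class:`GroundTruth`: the true neurite
forest (soma-root / junction / endpoint nodes, branch polylines with exact
lengths) and the morphometry computed analytically from it. The branching
probability is the density knob that maps to the knockout phenotype: halving
it thins the network, lowering branch and junction counts while lengthening
the surviving branches.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .image import Acquisition, Image2D, MorphometryRecord, save_image

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "MarkerScene",
    "PlacementError",
    "generate_acquisition",
    "generate_group",
    "generate_marker_scene",
    "as_stack",
    "write_cohort",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap in the field."""


@dataclass
class GeneratorParams:
    """Scene parameters; defaults emulate the study's imaging conditions.

    The field is 212.3 µm square at 0.207 µm/px (the published calibration);
    the raster spans the field rounded down to an even pixel count (1024 px
    by default). Intensity levels are implementer-chosen 16-bit values — the
    source imagery carries no published intensity statistics.
    """

    field_size_um: float = 212.3
    pixel_size_um: float = 0.207
    n_cells: int = 12
    nucleus_diameter_um_range: tuple[float, float] = (9.0, 15.0)
    neurites_per_cell_range: tuple[int, int] = (2, 4)
    branching_prob: float = 0.35
    mean_segment_len_um: float = 12.0
    min_segment_len_um: float = 6.0
    neurite_width_px_range: tuple[int, int] = (1, 3)
    signal_level: float = 8000.0
    background_level: float = 400.0
    soma_brightness_factor: float = 1.5
    noise_model: str = "poisson+gaussian"  # none | gaussian | poisson | poisson+gaussian
    read_noise_sd: float = 40.0
    photons_per_unit: float = 0.05
    dtype: str = "uint16"
    max_steps_per_path: int = 6
    max_branch_depth: int = 4
    angle_jitter_sd: float = 0.25
    branch_half_angle: float = 0.55
    branch_half_angle_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_size_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field_size_um and pixel_size_um must be positive")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching_prob must lie in [0, 1]")
        lo, hi = self.neurite_width_px_range
        if not (1 <= lo <= hi <= 5):
            raise ValueError("neurite_width_px_range must satisfy 1 <= min <= max <= 5")
        for name in ("nucleus_diameter_um_range", "neurites_per_cell_range"):
            a, b = getattr(self, name)
            if a > b:
                raise ValueError(f"{name} must have min <= max")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.noise_model not in {"none", "gaussian", "poisson", "poisson+gaussian"}:
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.dtype not in {"uint8", "uint16"}:
            raise ValueError("dtype must be 'uint8' or 'uint16'")

    @property
    def grid_px(self) -> int:
        """Raster side length: field extent rounded down to an even pixel count."""
        return 2 * int(self.field_size_um / (2.0 * self.pixel_size_um))


@dataclass
class GTNode:
    id: int
    x_um: float
    y_um: float
    kind: str  # 'soma-root' | 'junction' | 'endpoint'


@dataclass
class GTEdge:
    id: int
    node_a: int
    node_b: int
    polyline: list[tuple[float, float]]  # (x_um, y_um) vertices
    length_um: float
    width_px: int


@dataclass
class GroundTruth:
    """True scene geometry and the morphometry it implies."""

    cell_centers: list[tuple[float, float]]
    cell_radii_um: list[float]
    nodes: list[GTNode]
    edges: list[GTEdge]
    true_metrics: MorphometryRecord

    def to_json(self) -> str:
        payload = {
            "cell_centers": self.cell_centers,
            "cell_radii_um": self.cell_radii_um,
            "nodes": [dataclasses.asdict(n) for n in self.nodes],
            "edges": [dataclasses.asdict(e) for e in self.edges],
            "true_metrics": self.true_metrics.as_dict(),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _polyline_length(points: list[tuple[float, float]]) -> float:
    return float(
        sum(
            math.hypot(points[i + 1][0] - points[i][0], points[i + 1][1] - points[i][1])
            for i in range(len(points) - 1)
        )
    )


def _clip_to_field(p0, p1, size: float):
    """Truncate segment p0->p1 at the field boundary; None if no motion remains."""
    x0, y0 = p0
    x1, y1 = p1
    t = 1.0
    for lo_hi, a, b in (((0.0, size), x0, x1), ((0.0, size), y0, y1)):
        lo, hi = lo_hi
        if b < lo and b != a:
            t = min(t, (lo - a) / (b - a))
        elif b > hi and b != a:
            t = min(t, (hi - a) / (b - a))
    if t <= 1e-9:
        return None
    return (x0 + t * (x1 - x0), y0 + t * (y1 - y0)), t < 1.0


def _place_cells(params: GeneratorParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping nuclei (centers + radii, µm)."""
    cells: list[tuple[float, float, float]] = []
    d_lo, d_hi = params.nucleus_diameter_um_range
    size = params.field_size_um
    max_tries = 400 * max(params.n_cells, 1)
    tries = 0
    while len(cells) < params.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {params.n_cells} non-overlapping nuclei "
                f"(diameters {d_lo}-{d_hi} um) in a {size} x {size} um field "
                f"after {max_tries} attempts"
            )
        tries += 1
        r = 0.5 * rng.uniform(d_lo, d_hi)
        margin = r + 2.5
        x = rng.uniform(margin, size - margin)
        y = rng.uniform(margin, size - margin)
        if all(math.hypot(x - cx, y - cy) >= r + cr + 2.5 for cx, cy, cr in cells):
            cells.append((x, y, r))
    return cells


def _grow_forest(params: GeneratorParams, rng: np.random.Generator, cells):
    """Grow each cell's neurite trees; returns (nodes, edges)."""
    nodes: list[GTNode] = []
    edges: list[GTEdge] = []

    def add_node(x, y, kind) -> int:
        nodes.append(GTNode(len(nodes), x, y, kind))
        return len(nodes) - 1

    w_lo, w_hi = params.neurite_width_px_range
    n_lo, n_hi = params.neurites_per_cell_range
    for cx, cy, cr in cells:
        n_neurites = int(rng.integers(n_lo, n_hi + 1))
        base = rng.uniform(0.0, 2.0 * math.pi)
        for k in range(n_neurites):
            theta = base + 2.0 * math.pi * k / max(n_neurites, 1) + rng.normal(
                0.0, 0.2
            )
            width = int(rng.integers(w_lo, w_hi + 1))
            rx = cx + cr * math.cos(theta)
            ry = cy + cr * math.sin(theta)
            clipped = _clip_to_field((cx, cy), (rx, ry), params.field_size_um)
            if clipped is None:
                continue
            (rx, ry), _ = clipped
            root = add_node(rx, ry, "soma-root")
            # LIFO stack of growing tips: (start node, position, angle, steps, depth)
            tips = [(root, (rx, ry), theta, 0, 0)]
            while tips:
                start_node, pos, ang, steps, depth = tips.pop()
                poly = [pos]
                while True:
                    ang += rng.normal(0.0, params.angle_jitter_sd)
                    # shifted exponential: consecutive branch points keep a
                    # minimum spacing, as real neurite arbors do
                    mean_tail = max(
                        params.mean_segment_len_um - params.min_segment_len_um, 0.1
                    )
                    seg = params.min_segment_len_um + rng.exponential(mean_tail)
                    target = (
                        pos[0] + seg * math.cos(ang),
                        pos[1] + seg * math.sin(ang),
                    )
                    clip = _clip_to_field(pos, target, params.field_size_um)
                    if clip is None:
                        end = add_node(pos[0], pos[1], "endpoint")
                        break
                    pos, hit_edge = clip
                    poly.append(pos)
                    steps += 1
                    if hit_edge or steps >= params.max_steps_per_path:
                        end = add_node(pos[0], pos[1], "endpoint")
                        break
                    if (
                        depth < params.max_branch_depth
                        and rng.random() < params.branching_prob
                    ):
                        end = add_node(pos[0], pos[1], "junction")
                        half = abs(
                            rng.normal(
                                params.branch_half_angle, params.branch_half_angle_sd
                            )
                        )
                        tips.append((end, pos, ang - half, steps, depth + 1))
                        tips.append((end, pos, ang + half, steps, depth + 1))
                        break
                if len(poly) >= 2:
                    edges.append(
                        GTEdge(
                            len(edges),
                            start_node,
                            end,
                            [tuple(p) for p in poly],
                            _polyline_length(poly),
                            width,
                        )
                    )
                else:
                    # zero-motion branch: demote its terminal back out of the graph
                    nodes.pop()
    return nodes, edges


def metrics_from_graph(
    nodes: list[GTNode], edges: list[GTEdge], n_somata: int
) -> MorphometryRecord:
    """Morphometry implied by a true graph: one branch per contracted edge."""
    n_branches = len(edges)
    n_junctions = sum(1 for n in nodes if n.kind == "junction")
    n_endpoints = sum(1 for n in nodes if n.kind == "endpoint")
    total = float(sum(e.length_um for e in edges))
    defined = n_branches > 0
    return MorphometryRecord(
        n_somata=n_somata,
        n_branches=n_branches,
        n_junctions=n_junctions,
        n_endpoints=n_endpoints,
        total_branch_length_um=total,
        avg_branch_length_um=total / n_branches if defined else 0.0,
        avg_length_defined=defined,
    )


def _apply_noise(
    expected: np.ndarray, params: GeneratorParams, rng: np.random.Generator
) -> np.ndarray:
    out = expected.astype(np.float64)
    if params.noise_model in ("poisson", "poisson+gaussian"):
        ppu = params.photons_per_unit
        out = rng.poisson(np.clip(out * ppu, 0.0, None)).astype(np.float64) / ppu
    if params.noise_model in ("gaussian", "poisson+gaussian"):
        out = out + rng.normal(0.0, params.read_noise_sd, size=out.shape)
    return out


def _quantize(values: np.ndarray, dtype: str) -> np.ndarray:
    top = np.iinfo(np.dtype(dtype)).max
    return np.clip(np.rint(values), 0, top).astype(dtype)


def _render_dapi(params, cells, rng) -> np.ndarray:
    n = params.grid_px
    canvas = np.zeros((n, n), dtype=np.float64)
    px = params.pixel_size_um
    for cx, cy, cr in cells:
        rr, cc = skdraw.disk((cy / px, cx / px), cr / px, shape=(n, n))
        canvas[rr, cc] = 1.0
    # ~0.6 um edge ramp: chromatin density falloff plus optical blur; also
    # lets the nuclear mask reach just past the somatic glow of the marker
    # channel, as it does in real acquisitions
    canvas = ndi.gaussian_filter(canvas, 3.0)
    expected = params.background_level + params.signal_level * canvas
    return _quantize(_apply_noise(expected, params, rng), params.dtype)


def _render_map2(params, cells, edges, rng) -> np.ndarray:
    n = params.grid_px
    px = params.pixel_size_um
    profile = np.zeros((n, n), dtype=np.float64)
    widths = sorted({e.width_px for e in edges})
    for w in widths:
        centerline = np.zeros((n, n), dtype=bool)
        for e in edges:
            if e.width_px != w:
                continue
            pts = [
                (
                    min(max(int(round(y / px)), 0), n - 1),
                    min(max(int(round(x / px)), 0), n - 1),
                )
                for x, y in e.polyline
            ]
            for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
                rr, cc = skdraw.line(r0, c0, r1, c1)
                centerline[rr, cc] = True
        if not centerline.any():
            continue
        dist = ndi.distance_transform_edt(~centerline)
        sigma = max(w / 2.0, 0.6)
        contrib = np.exp(-(dist**2) / (2.0 * sigma**2))
        contrib[dist > w / 2.0 + 1.5] = 0.0  # hard support bound: channel separation
        np.maximum(profile, contrib, out=profile)
    soma = np.zeros((n, n), dtype=np.float64)
    for cx, cy, cr in cells:
        rr, cc = skdraw.disk((cy / px, cx / px), cr / px, shape=(n, n))
        soma[rr, cc] = params.soma_brightness_factor
    body = np.maximum(profile, soma)
    expected = params.background_level + params.signal_level * body
    return _quantize(_apply_noise(expected, params, rng), params.dtype)


def geometry_support(params: GeneratorParams, truth: "GroundTruth") -> np.ndarray:
    """Boolean raster of the rendered neurite+soma support (noise-free extent)."""
    n = params.grid_px
    px = params.pixel_size_um
    support = np.zeros((n, n), dtype=bool)
    widths = sorted({e.width_px for e in truth.edges})
    for w in widths:
        centerline = np.zeros((n, n), dtype=bool)
        for e in truth.edges:
            if e.width_px != w:
                continue
            pts = [
                (
                    min(max(int(round(y / px)), 0), n - 1),
                    min(max(int(round(x / px)), 0), n - 1),
                )
                for x, y in e.polyline
            ]
            for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
                rr, cc = skdraw.line(r0, c0, r1, c1)
                centerline[rr, cc] = True
        if centerline.any():
            dist = ndi.distance_transform_edt(~centerline)
            support |= dist <= w / 2.0 + 1.5
    for (cx, cy), cr in zip(truth.cell_centers, truth.cell_radii_um):
        rr, cc = skdraw.disk((cy / px, cx / px), cr / px, shape=(n, n))
        support[rr, cc] = True
    return support


def generate_acquisition(
    params: GeneratorParams,
) -> tuple[Acquisition, GroundTruth]:
    """One synthetic two-channel acquisition plus its ground truth.

    Deterministic for a fixed ``params.seed``: two calls with identical
    parameters produce bit-identical rasters and identical ground truth.
    """
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    nodes, edges = _grow_forest(params, rng, cells)
    truth = GroundTruth(
        cell_centers=[(c[0], c[1]) for c in cells],
        cell_radii_um=[c[2] for c in cells],
        nodes=nodes,
        edges=edges,
        true_metrics=metrics_from_graph(nodes, edges, n_somata=len(cells)),
    )
    dapi = _render_dapi(params, cells, rng)
    map2 = _render_map2(params, cells, edges, rng)
    acq = Acquisition(
        dapi=Image2D(dapi, params.pixel_size_um),
        map2=Image2D(map2, params.pixel_size_um),
        pixel_size_um=params.pixel_size_um,
        provenance=params,
    )
    return acq, truth


def as_stack(acq: Acquisition, n_planes: int = 3) -> Acquisition:
    """Emulate a z-stack: dimmed copies around the in-focus plane.

    The in-focus plane equals the single-plane image and the others are
    scaled below it, so a maximum-intensity projection recovers the
    single-plane image exactly.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    factors = [0.5 + 0.5 * (1.0 - abs(i - (n_planes - 1) / 2) / max((n_planes - 1) / 2, 1))
               for i in range(n_planes)]
    mid = n_planes // 2
    factors[mid] = 1.0

    def planes(img: Image2D) -> list[Image2D]:
        out = []
        for f in factors:
            if f >= 1.0:
                out.append(img.with_values(img.values.copy()))
            else:
                out.append(img.with_values((img.values * f).astype(img.values.dtype)))
        return out

    return Acquisition(
        dapi=acq.dapi,
        map2=acq.map2,
        pixel_size_um=acq.pixel_size_um,
        dapi_stack=planes(acq.dapi),
        map2_stack=planes(acq.map2),
        image_id=acq.image_id,
        group=acq.group,
        replicate=acq.replicate,
        provenance=acq.provenance,
    )


@dataclass
class CohortItem:
    group: str
    replicate: int
    index: int
    seed: int
    acquisition: Acquisition
    ground_truth: GroundTruth


def generate_cohort(
    group_params: dict[str, GeneratorParams],
    n_images_per_replicate: int,
    n_replicates: int = 3,
    master_seed: int = 0,
) -> list[CohortItem]:
    """A multi-group cohort with per-image seeds derived from a master seed.

    ``n_images_per_replicate`` acquisitions per replicate and group (so 10
    images over 3 replicates yields 30 acquisitions per group).
    """
    if n_images_per_replicate < 1:
        raise ValueError("n_images_per_replicate must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(group_params) * n_replicates * n_images_per_replicate)
    items: list[CohortItem] = []
    child_i = 0
    for gname, gparams in group_params.items():
        for rep in range(1, n_replicates + 1):
            for idx in range(n_images_per_replicate):
                seed = int(children[child_i].generate_state(1, np.uint32)[0])
                child_i += 1
                p = dataclasses.replace(gparams, seed=seed)
                acq, truth = generate_acquisition(p)
                acq.image_id = f"{gname}_r{rep}_i{idx:02d}"
                acq.group = gname
                acq.replicate = rep
                truth.true_metrics.image_id = acq.image_id
                truth.true_metrics.group = gname
                truth.true_metrics.replicate = rep
                items.append(CohortItem(gname, rep, idx, seed, acq, truth))
    return items


def generate_group(
    params_wt: GeneratorParams,
    params_ko: GeneratorParams,
    n_images_per_group: int,
    n_replicates: int = 3,
    master_seed: int = 0,
    group_names: tuple[str, str] = ("WT", "KO"),
) -> list[CohortItem]:
    """Two-group convenience wrapper around :func:`generate_cohort`.

    The knockout group is emulated by the caller's ``params_ko`` — typically
    the wild-type parameters with a lower branching probability and/or fewer
    neurites per cell, holding ``n_cells`` fixed so soma counts match.
    """
    return generate_cohort(
        {group_names[0]: params_wt, group_names[1]: params_ko},
        n_images_per_replicate=n_images_per_group,
        n_replicates=n_replicates,
        master_seed=master_seed,
    )


@dataclass
class MarkerScene:
    """Nuclear channel plus two marker channels with per-cell positivity truth."""

    nuclei: Image2D
    chat: Image2D
    islet1: Image2D
    cell_centers: list[tuple[float, float]]
    chat_positive: list[bool]
    islet1_positive: list[bool]

    @property
    def double_positive_fraction(self) -> float:
        if not self.cell_centers:
            return 0.0
        both = sum(a and b for a, b in zip(self.chat_positive, self.islet1_positive))
        return both / len(self.cell_centers)


def generate_marker_scene(
    params: GeneratorParams,
    chat_positive: list[bool] | None = None,
    islet1_positive: list[bool] | None = None,
    p_chat: float = 0.7,
    p_islet1: float = 0.8,
) -> MarkerScene:
    """A scoring scene: nuclei plus CHAT/ISLET1 channels bright in known cells."""
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    ncells = len(cells)
    if chat_positive is None:
        chat_positive = list(rng.random(ncells) < p_chat)
    if islet1_positive is None:
        islet1_positive = list(rng.random(ncells) < p_islet1)
    if len(chat_positive) != ncells or len(islet1_positive) != ncells:
        raise ValueError("positivity flags must match the number of cells")

    nuclei = _render_dapi(params, cells, rng)

    def marker(flags: list[bool]) -> np.ndarray:
        n = params.grid_px
        canvas = np.zeros((n, n), dtype=np.float64)
        px = params.pixel_size_um
        for (cx, cy, cr), pos in zip(cells, flags):
            if pos:
                rr, cc = skdraw.disk((cy / px, cx / px), cr / px, shape=(n, n))
                canvas[rr, cc] = 1.0
        expected = params.background_level + params.signal_level * canvas
        return _quantize(_apply_noise(expected, params, rng), params.dtype)

    chat = marker(chat_positive)
    islet1 = marker(islet1_positive)
    return MarkerScene(
        nuclei=Image2D(nuclei, params.pixel_size_um),
        chat=Image2D(chat, params.pixel_size_um),
        islet1=Image2D(islet1, params.pixel_size_um),
        cell_centers=[(c[0], c[1]) for c in cells],
        chat_positive=[bool(b) for b in chat_positive],
        islet1_positive=[bool(b) for b in islet1_positive],
    )


def write_cohort(items: list[CohortItem], out_dir: str | Path) -> Path:
    """Write TIFF pairs, ground-truth JSON/CSV, and a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    truth_csv = out / "true_metrics.csv"
    with open(manifest, "w", newline="") as mf, open(truth_csv, "w", newline="") as tf:
        mw = csv.writer(mf)
        mw.writerow(["image_id", "group", "replicate", "index", "seed",
                     "dapi_path", "map2_path", "pixel_size_um"])
        tw = csv.DictWriter(tf, fieldnames=list(MorphometryRecord().as_dict()))
        tw.writeheader()
        for it in items:
            stem = it.acquisition.image_id
            dapi_path = out / f"{stem}_dapi.tif"
            map2_path = out / f"{stem}_map2.tif"
            save_image(it.acquisition.dapi, dapi_path)
            save_image(it.acquisition.map2, map2_path)
            (out / f"{stem}_truth.json").write_text(it.ground_truth.to_json())
            mw.writerow([stem, it.group, it.replicate, it.index, it.seed,
                         dapi_path.name, map2_path.name,
                         it.acquisition.pixel_size_um])
            tw.writerow(it.ground_truth.true_metrics.as_dict())
    return manifest
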