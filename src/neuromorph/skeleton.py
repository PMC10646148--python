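"""Skeletonization and skeleton-graph morphometry.

The neurite mask is thinned to unit-width 8-connected centerlines, then each
skeleton pixel is classified by its number of skeleton neighbors:

* endpoint — 0 or 1 neighbors (an isolated pixel counts as an endpoint),
* slab — exactly 2 neighbors,
* junction — 3 or more neighbors.

Mutually adjacent junction pixels are merged into a single junction cluster
(one junction node per cluster, the usual skeleton-analysis convention). A
*branch* is a maximal slab path between two terminals (endpoint or junction
cluster); its physical length accumulates one pixel size per orthogonal step
and sqrt(2) pixel sizes per diagonal step. Isolated closed loops are single
branches of their full cycle length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.morphology import skeletonize as _sk_skeletonize

from .image import Acquisition, BinaryMask, Image2D, MorphometryRecord, max_project
from .masking import MaskingParams, build_neurite_mask, build_nuclei_mask

logger = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1),           (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass
class Branch:
    """One skeleton branch: its pixel path, terminal kinds, and length."""

    path: list[tuple[int, int]]
    kind_a: str  # 'endpoint' | 'junction' | 'loop' | 'isolated'
    kind_b: str
    length_um: float


@dataclass
class SkeletonGraph:
    """Classified skeleton with branch decomposition."""

    skeleton: np.ndarray                 # bool raster
    pixel_size_um: float
    neighbor_counts: np.ndarray          # int raster, 0 off-skeleton
    voxel_class: np.ndarray              # 0 off, 1 endpoint, 2 slab, 3 junction
    junction_labels: np.ndarray          # int raster, cluster id per junction px
    n_junction_clusters: int
    branches: list[Branch] = field(default_factory=list)

    ENDPOINT, SLAB, JUNCTION = 1, 2, 3

    @property
    def n_endpoints(self) -> int:
        return int(np.count_nonzero(self.voxel_class == self.ENDPOINT))

    @property
    def n_junctions(self) -> int:
        return self.n_junction_clusters

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_branch_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Topology-preserving thinning to unit-width centerlines.

    Uses Zhang-style iterative border-deletion thinning (scikit-image),
    iterated to a fixed point so the operation is idempotent: a skeleton
    re-skeletonizes to itself. The skeleton is a subset of the mask and
    preserves the number of 8-connected components. Zhang's scan order can
    leave a one-pixel kink at the very end of a symmetric ribbon; the
    centerline still spans the ribbon as a single unit-width path.
    """
    values = np.asarray(mask.values, dtype=bool)
    if not values.any():
        return mask.with_values(values)
    out = _sk_skeletonize(values)
    for _ in range(4):  # fixed-point guard; converges in 1-2 passes
        again = _sk_skeletonize(out)
        if np.array_equal(again, out):
            break
        out = again
    return mask.with_values(out)


def _neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    counts = ndi.convolve(skeleton.astype(int), kernel, mode="constant", cval=0)
    counts[~skeleton] = 0
    return counts


def classify_voxels(skeleton: BinaryMask) -> SkeletonGraph:
    """Classify skeleton pixels as endpoint / slab / junction and cluster junctions."""
    sk = np.asarray(skeleton.values, dtype=bool)
    counts = _neighbor_counts(sk)
    voxel_class = np.zeros(sk.shape, dtype=np.uint8)
    voxel_class[sk & (counts <= 1)] = SkeletonGraph.ENDPOINT
    voxel_class[sk & (counts == 2)] = SkeletonGraph.SLAB
    voxel_class[sk & (counts >= 3)] = SkeletonGraph.JUNCTION
    if np.any(counts > 4):
        logger.warning(
            "classify_voxels: %d pixel(s) with >4 neighbors; input may not be unit-width",
            int(np.count_nonzero(counts > 4)),
        )
    junction_labels, n_clusters = measure.label(
        voxel_class == SkeletonGraph.JUNCTION, connectivity=2, return_num=True
    )
    return SkeletonGraph(
        skeleton=sk,
        pixel_size_um=skeleton.pixel_size_um,
        neighbor_counts=counts,
        voxel_class=voxel_class,
        junction_labels=junction_labels,
        n_junction_clusters=int(n_clusters),
    )


def _step_length(a: tuple[int, int], b: tuple[int, int]) -> float:
    return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _path_length_px(path: list[tuple[int, int]]) -> float:
    return float(sum(_step_length(path[i], path[i + 1]) for i in range(len(path) - 1)))


def extract_branches(graph: SkeletonGraph, pixel_size_um: float | None = None) -> SkeletonGraph:
    """Decompose a classified skeleton into branches with physical lengths.

    Walks every maximal slab path between terminals, records direct
    terminal-terminal adjacencies as unit branches, and reports isolated
    closed loops as single branches of their cycle length. An isolated
    single pixel is an endpoint voxel but contributes no branch: branches
    are paths between terminals and always have positive length.
    """
    px = graph.pixel_size_um if pixel_size_um is None else pixel_size_um
    sk = graph.skeleton
    cls = graph.voxel_class
    jl = graph.junction_labels
    H, W = sk.shape

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = p
        out = []
        for dr, dc in _NEIGHBOR_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and sk[rr, cc]:
                out.append((rr, cc))
        return out

    def kind(p: tuple[int, int]) -> str:
        k = cls[p]
        return "endpoint" if k == SkeletonGraph.ENDPOINT else (
            "junction" if k == SkeletonGraph.JUNCTION else "slab"
        )

    branches: list[Branch] = []
    visited_slab: set[tuple[int, int]] = set()
    direct_pairs: set[frozenset] = set()

    terminal_pixels = [tuple(p) for p in np.argwhere((cls == 1) | (cls == 3))]
    for t in terminal_pixels:
        nbrs = neighbors(t)
        if not nbrs and cls[t] == SkeletonGraph.ENDPOINT:
            # isolated single pixel: an endpoint voxel but no edge, hence no
            # branch (branches are paths between terminals and have length > 0)
            continue
        for n in nbrs:
            if cls[n] != SkeletonGraph.SLAB:
                # direct terminal-terminal adjacency
                if cls[t] == cls[n] == SkeletonGraph.JUNCTION and jl[t] == jl[n]:
                    continue  # intra-cluster edge, not a branch
                key = frozenset((t, n))
                if key in direct_pairs:
                    continue
                direct_pairs.add(key)
                path = [t, n]
                branches.append(
                    Branch(path, kind(t), kind(n), _path_length_px(path) * px)
                )
                continue
            if n in visited_slab:
                continue
            # walk the slab run starting at n until the next terminal
            path = [t, n]
            visited_slab.add(n)
            prev, cur = t, n
            while True:
                nxt = [q for q in neighbors(cur) if q != prev]
                if not nxt:  # dangling slab (should not happen on clean input)
                    break
                step = nxt[0]
                if cls[step] == SkeletonGraph.SLAB:
                    if step in visited_slab:  # tight slab cycle back onto path
                        path.append(step)
                        break
                    visited_slab.add(step)
                    path.append(step)
                    prev, cur = cur, step
                else:
                    path.append(step)
                    break
            branches.append(
                Branch(path, kind(path[0]), kind(path[-1]), _path_length_px(path) * px)
            )

    # isolated cycles: slab pixels never reached from any terminal
    remaining = [
        tuple(p)
        for p in np.argwhere(cls == SkeletonGraph.SLAB)
        if tuple(p) not in visited_slab
    ]
    remaining_set = set(remaining)
    while remaining_set:
        start = min(remaining_set)  # deterministic pick
        path = [start]
        remaining_set.discard(start)
        prev, cur = None, start
        while True:
            nbrs = [q for q in neighbors(cur) if q != prev]
            step = nbrs[0] if nbrs else None
            if step is None or step == start:
                break
            path.append(step)
            remaining_set.discard(step)
            prev, cur = cur, step
        closed = path + [start]
        branches.append(Branch(closed, "loop", "loop", _path_length_px(closed) * px))

    graph.branches = branches
    return graph


def count_somata(nuclei_mask: BinaryMask) -> int:
    """Number of 8-connected components in the pre-expansion nuclei mask."""
    _, n = measure.label(nuclei_mask.values, connectivity=2, return_num=True)
    return int(n)


def morphometry_from_graph(
    graph: SkeletonGraph,
    n_somata: int = 0,
    image_id: str = "",
    group: str = "",
    replicate: int = 0,
) -> MorphometryRecord:
    total = graph.total_branch_length_um
    n_branches = graph.n_branches
    defined = n_branches > 0
    avg = total / n_branches if defined else 0.0
    return MorphometryRecord(
        image_id=image_id,
        group=group,
        replicate=replicate,
        n_somata=n_somata,
        n_branches=n_branches,
        n_junctions=graph.n_junctions,
        n_endpoints=graph.n_endpoints,
        total_branch_length_um=total,
        avg_branch_length_um=avg,
        avg_length_defined=defined,
    )


def measure_acquisition(
    acq: Acquisition, params: MaskingParams | None = None
) -> MorphometryRecord:
    """Full measurement pipeline for one acquisition.

    Z-stacks are max-projected; the DAPI channel yields the nuclei/soma
    masks, the Map2 channel the neurite mask; the mask is skeletonized and
    walked for branch/junction/endpoint counts and lengths. A blank Map2
    channel produces a zero-branch record (average length 0, flagged).
    """
    params = params or MaskingParams()
    dapi = max_project(acq.dapi_stack) if acq.dapi_stack else acq.dapi
    map2 = max_project(acq.map2_stack) if acq.map2_stack else acq.map2
    nuclei, soma = build_nuclei_mask(dapi, params)
    neurite = build_neurite_mask(map2, soma, params)
    sk = skeletonize(neurite)
    graph = extract_branches(classify_voxels(sk))
    record = morphometry_from_graph(
        graph,
        n_somata=count_somata(nuclei),
        image_id=acq.image_id,
        group=acq.group,
        replicate=acq.replicate,
    )
    if record.n_branches == 0:
        logger.info(
            "measure_acquisition(%s): no branches; average branch length reported as 0",
            acq.image_id or "<unnamed>",
        )
    return record


def skeleton_overlay(sk: BinaryMask, image: Image2D) -> Image2D:
    """8-bit overlay of a skeleton (white) on a dimmed source image."""
    base = np.asarray(image.values, dtype=np.float64)
    top = base.max() or 1.0
    out = (base / top * 180).astype(np.uint8)
    out[sk.values] = 255
    return image.with_values(out)
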