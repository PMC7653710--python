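"""Microglial skeleton morphometry.

Binary microglia masks are thinned to 1-pixel-wide skeletons
(two-subiteration homotopic thinning, via scikit-image) and per-cell
metrics are computed: process endpoints (pixels with at most one skeleton
neighbor in the 8-neighborhood), branch points (clusters of pixels with
three or more neighbors; adjacent junction pixels count as one junction),
and total process length (each adjacent pixel pair counted once: 1 pixel
for orthogonal, sqrt(2) for diagonal steps, scaled by the pixel size —
the conventions of the standard skeleton-analysis plugin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import thin as _thin

STRUCTURE_8 = np.ones((3, 3), dtype=int)

SQRT2 = float(np.sqrt(2.0))


class NotThinError(ValueError):
    """Raised when skeleton metrics are requested for a non-thin mask."""


@dataclass
class SkeletonMetrics:
    cell_id: int
    endpoints: int
    branch_points: int
    total_length_um: float
    branch_lengths_um: list = field(default_factory=list)
    n_pixels: int = 0


@dataclass
class CellSelection:
    """Outcome of single-cell selection on skeleton components."""

    cells: list  # (cell_id, skeleton crop, slices)
    rejected_merged: int
    rejected_fragment: int
    rejected_size: int


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Morphological thinning to 1-px-wide curves.

    Two-subiteration homotopic thinning run to completion (maximally
    thin).  The skeleton is a subset of the mask, preserves the number of
    connected components, and is a fixed point of the thinning operator.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if not mask.any():
        return np.zeros_like(mask)
    return _thin(mask).astype(bool)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    """Number of 8-neighbors of every skeleton pixel."""
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    return ndi.convolve(skel.astype(int), kernel, mode="constant", cval=0)


def _check_thin(skel: np.ndarray) -> None:
    """Reject masks containing a filled 2x3 (or 3x2) block.

    Thinned skeletons never contain such blocks; 2x2 blocks around
    minimal 1-px holes are allowed (homotopic thinning cannot remove
    them without changing topology).  The check is invariant under
    90-degree rotation.
    """
    b23 = (
        skel[:-1, :-2] & skel[:-1, 1:-1] & skel[:-1, 2:]
        & skel[1:, :-2] & skel[1:, 1:-1] & skel[1:, 2:]
    )
    b32 = (
        skel[:-2, :-1] & skel[1:-1, :-1] & skel[2:, :-1]
        & skel[:-2, 1:] & skel[1:-1, 1:] & skel[2:, 1:]
    )
    for block in (b23, b32):
        if block.any():
            y, x = np.argwhere(block)[0]
            raise NotThinError(f"skeleton is not 1-px wide at pixel ({y}, {x})")


def _adjacency_edges(skel: np.ndarray) -> list[tuple[tuple, tuple, float]]:
    """All adjacent skeleton pixel pairs, each counted once, with step weight."""
    pix = set(map(tuple, np.argwhere(skel)))
    edges = []
    # half of the 8 directions, so each unordered pair appears exactly once
    for dy, dx, wgt in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)):
        for (y, x) in pix:
            nb = (y + dy, x + dx)
            if nb in pix:
                edges.append(((y, x), nb, wgt))
    return edges


def skeleton_metrics(
    skeleton: np.ndarray, pixel_size_um: float, cell_id: int = 0
) -> SkeletonMetrics:
    """Endpoint / branch-point counts and process length of one skeleton.

    An isolated pixel counts as one endpoint with zero length.  Raises
    :class:`NotThinError` (with the offending pixel) for non-thin input.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not skel.any():
        return SkeletonMetrics(cell_id, 0, 0, 0.0, [], 0)
    _check_thin(skel)
    nbrs = _neighbor_count(skel)
    endpoints = int(((nbrs <= 1) & skel).sum())
    # adjacent junction pixels form one junction (the skeleton-plugin
    # convention): count 8-connected clusters of >=3-neighbor pixels
    _, branch_points = ndi.label((nbrs >= 3) & skel, structure=STRUCTURE_8)
    edges = _adjacency_edges(skel)
    branch_lengths = _branch_lengths(skel, nbrs, edges, pixel_size_um)
    total = float(sum(w for _, _, w in edges)) * pixel_size_um
    return SkeletonMetrics(
        cell_id=cell_id,
        endpoints=endpoints,
        branch_points=branch_points,
        total_length_um=total,
        branch_lengths_um=branch_lengths,
        n_pixels=int(skel.sum()),
    )


def _branch_lengths(skel, nbrs, edges, pixel_size_um) -> list[float]:
    """Partition the skeleton's adjacency edges into branches.

    Branches are the connected runs of edges obtained after conceptually
    cutting the skeleton at its branch points; every edge belongs to
    exactly one branch, so branch lengths sum to the total length.
    """
    import networkx as nx

    if not edges:
        return []
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    junctions = {tuple(p) for p in np.argwhere((nbrs >= 3) & skel)}
    # edges incident to a junction seed their own branch; the rest group
    # into the path components left after removing junction nodes
    lengths = []
    seen = set()

    def edge_key(a, b):
        return (a, b) if a <= b else (b, a)

    h = g.copy()
    h.remove_nodes_from(junctions)
    for comp in nx.connected_components(h):
        total = 0.0
        for a, b, data in g.edges(comp, data=True):
            k = edge_key(a, b)
            if k in seen:
                continue
            seen.add(k)
            total += data["weight"]
        if total > 0:
            lengths.append(total * pixel_size_um)
    # leftover edges connect junctions directly to each other
    leftover = 0.0
    for a, b, data in g.edges(data=True):
        k = edge_key(a, b)
        if k not in seen:
            seen.add(k)
            leftover += data["weight"]
    if leftover > 0:
        lengths.append(leftover * pixel_size_um)
    return lengths


def process_endpoint_count(
    skeleton: np.ndarray,
    soma_center_px: tuple,
    soma_radius_px: float,
    margin_px: float = 1.0,
) -> int:
    """Number of process tips of one cell's skeleton.

    Counts skeleton endpoints lying outside the soma body (beyond
    ``soma_radius_px + margin_px`` of the soma center).  Thinning a soma
    disk with attached processes can leave short spur endpoints inside
    the body; those are artifacts of the thinning, not process tips, and
    are excluded here.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        return 0
    nbrs = _neighbor_count(skel)
    ys, xs = np.nonzero((nbrs <= 1) & skel)
    cy, cx = soma_center_px
    dist = np.hypot(ys - cy, xs - cx)
    return int((dist > soma_radius_px + margin_px).sum())


def select_cells(
    skeleton: np.ndarray,
    soma_centroids_um: list[tuple[float, float]],
    pixel_size_um: float,
    length_min_um: float = 5.0,
    length_max_um: float = 500.0,
    soma_tolerance_um: float = 5.0,
) -> CellSelection:
    """Select skeleton components that represent individual microglia.

    Automated proxy for the visual single-cell selection step: a component
    is kept when its total process length lies in ``[length_min_um,
    length_max_um]`` and exactly one soma centroid lies within
    ``soma_tolerance_um`` of it.  Components claiming several somata are
    flagged as merged and rejected; soma-less fragments are rejected.
    """
    skel = np.asarray(skeleton, dtype=bool)
    labels, n = ndi.label(skel, structure=STRUCTURE_8)
    cells, merged, fragment, size = [], 0, 0, 0
    if n == 0:
        return CellSelection([], 0, 0, 0)
    objects = ndi.find_objects(labels)
    tol_px = soma_tolerance_um / pixel_size_um
    soma_px = [(y / pixel_size_um, x / pixel_size_um) for y, x in soma_centroids_um]
    for lab, slc in enumerate(objects, start=1):
        crop = labels[slc] == lab
        pix = np.argwhere(crop) + [slc[0].start, slc[1].start]
        n_somata = 0
        for (sy, sx) in soma_px:
            d2 = (pix[:, 0] - sy) ** 2 + (pix[:, 1] - sx) ** 2
            if d2.min() <= tol_px**2:
                n_somata += 1
        if n_somata == 0:
            fragment += 1
            continue
        if n_somata > 1:
            merged += 1
            continue
        m = skeleton_metrics(crop, pixel_size_um, cell_id=lab - 1)
        if not length_min_um <= m.total_length_um <= length_max_um:
            size += 1
            continue
        cells.append((lab - 1, crop, slc))
    return CellSelection(cells=cells, rejected_merged=merged,
                         rejected_fragment=fragment, rejected_size=size)
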