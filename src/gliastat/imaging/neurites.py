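"""Neurite-network scoring: skeletonization, branch lengths and the
area-normalized damage rule.

The neurite (beta3-tubulin) signal inside an ROI is masked, skeletonized,
and decomposed into branch segments running between skeleton endpoints and
junctions.  Segment length sums pixel steps with diagonal steps weighted
sqrt(2).  The score per ROI is the median branch length divided by the ROI
area (um per um^2); an ROI whose score falls to half of the matched
control density or below is classified as damage-associated.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from gliastat.imaging.types import ImageScene

logger = logging.getLogger(__name__)

__all__ = [
    "skeleton_branch_lengths",
    "neurite_length_density",
    "classify_damage_associated",
    "noncluster_control_density",
]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _branch_segments(skeleton: np.ndarray) -> list[tuple[float, int, int]]:
    """Branch segments of a 1-px skeleton as (length_px, deg_end_a, deg_end_b).

    Node pixels have degree != 2 in 8-connectivity (endpoints and
    junctions); adjacent node pixels are merged into one super-node, as
    skeleton-graph tools do, so the dense junction clusters a rasterized
    crossing produces do not generate spurious 1-step branches.  A segment
    is the path between two super-nodes through degree-2 pixels; its end
    degrees are reported as 1 for a free endpoint and 3 for a junction
    cluster.  Isolated cycles count as one closed segment with end degrees
    (2, 2).
    """
    coords = np.argwhere(skeleton)
    if coords.size == 0:
        return []
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    nbrs: list[list[int]] = [[] for _ in range(len(coords))]
    for (r, c), i in index.items():
        for dr, dc in _OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append(j)

    def step(i: int, j: int) -> float:
        d = abs(coords[i][0] - coords[j][0]) + abs(coords[i][1] - coords[j][1])
        return np.sqrt(2.0) if d == 2 else 1.0

    deg = np.array([len(n) for n in nbrs])
    is_node = deg != 2

    # union-find over adjacent node pixels -> super-nodes
    parent = list(range(len(coords)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in np.flatnonzero(is_node):
        for j in nbrs[i]:
            if is_node[j]:
                parent[find(i)] = find(j)
    cluster = {int(i): find(int(i)) for i in np.flatnonzero(is_node)}
    cluster_size: dict[int, int] = {}
    for root in cluster.values():
        cluster_size[root] = cluster_size.get(root, 0) + 1

    def end_degree(i: int) -> int:
        # 1 = free endpoint (single-pixel cluster of degree <= 1), 3 = junction
        root = cluster[i]
        if cluster_size[root] == 1 and deg[i] <= 1:
            return 1
        return 3

    segments: list[tuple[float, int, int]] = []
    visited_edges: set[tuple[int, int]] = set()

    def edge(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    for start in sorted(np.flatnonzero(is_node)):
        start = int(start)
        for first in nbrs[start]:
            if is_node[first]:
                continue  # intra-cluster adjacency, not a branch
            if edge(start, first) in visited_edges:
                continue
            length = step(start, first)
            visited_edges.add(edge(start, first))
            prev, cur = start, first
            while not is_node[cur]:
                nxt = [k for k in nbrs[cur] if k != prev]
                if not nxt:
                    break  # defensive: degree-2 chain ending unexpectedly
                nxt = nxt[0]
                length += step(cur, nxt)
                visited_edges.add(edge(cur, nxt))
                prev, cur = cur, nxt
            end_deg = end_degree(int(cur)) if is_node[cur] else 1
            segments.append((length, end_degree(start), end_deg))

    # isolated fragments made entirely of node pixels (2-3 px debris) never
    # start a walk; report each as one short open segment of (size-1) steps
    touched = {i for e in visited_edges for i in e}
    roots_touched = {cluster[i] for i in touched if i in cluster}
    for root, size in cluster_size.items():
        if root in roots_touched:
            continue
        members = [i for i, r in cluster.items() if r == root]
        if any(not is_node[j] for i in members for j in nbrs[i]):
            continue  # has a branch walk elsewhere
        # a fragment's measurable length is at least its own pixel extent
        segments.append((float(max(size - 1, 1)), 1, 1))

    # pure cycles have every pixel at degree 2:
    remaining = set(map(int, np.flatnonzero(deg == 2))) - touched
    while remaining:
        start = remaining.pop()
        length, prev, cur = 0.0, None, start
        while True:
            nxt = [k for k in nbrs[cur] if k != prev]
            if not nxt:
                break
            nxt = nxt[0]
            length += step(cur, nxt)
            remaining.discard(nxt)
            prev, cur = cur, nxt
            if cur == start:
                break
        segments.append((length, 2, 2))

    return segments


def skeleton_branch_lengths(
    skeleton: np.ndarray, pixel_size: float = 1.0, prune_spur_um: float = 0.0
) -> np.ndarray:
    """Lengths (um) of skeleton branch segments.

    `prune_spur_um` drops terminal spurs — segments shorter than the given
    length that run from a junction to a free endpoint.  Skeletons of
    rasterized ribbons sprout 1-2 px spurs at crossings and bends; pruning
    removes those without touching isolated fragments, whose shortness is
    the signal the damage rule relies on.  Isolated single-pixel fragments
    count with a length of one pixel (their own extent).
    """
    segs = _branch_segments(skeleton)
    out = []
    for length, da, db in segs:
        um = length * pixel_size
        if um <= 0:
            continue
        is_spur = (min(da, db) <= 1 <= max(da, db) - 2) and um < prune_spur_um
        if is_spur:
            continue
        out.append(um)
    return np.asarray(out)


def neurite_length_density(
    scene: ImageScene,
    roi_mask: np.ndarray,
    channel: str = "TUBB3",
    threshold: float | None = None,
    prune_spur_um: float = 3.0,
) -> float:
    """Median skeleton branch length in the ROI divided by the ROI area.

    Units: um per um^2.  Returns 0 (logged) when the ROI holds no neurite
    signal.  Terminal spurs shorter than `prune_spur_um` are pruned (see
    `skeleton_branch_lengths`).
    """
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    img = scene.channel(channel)
    if threshold is None:
        threshold = threshold_otsu(img) if img.max() > img.min() else np.inf
    mask = (img > threshold) & roi_mask
    roi_area = float(roi_mask.sum()) * scene.pixel_area
    if not mask.any():
        logger.info("no neurite pixels in ROI; density 0")
        return 0.0
    skel = skeletonize(mask)
    lengths = skeleton_branch_lengths(skel, scene.pixel_size, prune_spur_um=prune_spur_um)
    if lengths.size == 0:
        return 0.0
    return float(np.median(lengths)) / roi_area


def classify_damage_associated(cluster_density: float, control_density: float) -> bool:
    """Damage call: at least a 50% reduction versus the control density.

    Boundary inclusive — exactly half the control density is damaged.
    """
    if control_density <= 0:
        raise ValueError("control density must be positive")
    return cluster_density <= 0.5 * control_density


def noncluster_control_density(
    scene: ImageScene,
    cluster_rois: list,
    roi_area_um2: float,
    channel: str = "TUBB3",
    threshold: float | None = None,
    n_samples: int = 8,
    seed: int = 0,
) -> float:
    """Control density from non-cluster regions, on area-matched disk ROIs.

    Disk ROIs of the requested area are dropped at random positions fully
    outside every expanded cluster ROI, and the median of their densities
    is returned — the 'non-cluster regions' control of the damage rule.
    """
    rng = np.random.default_rng(seed)
    shape = scene.shape
    excluded = np.zeros(shape, dtype=bool)
    for roi in cluster_rois:
        excluded |= roi.expanded_mask
    radius_px = int(round(np.sqrt(roi_area_um2 / np.pi) / scene.pixel_size))
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    densities = []
    tries = 0
    while len(densities) < n_samples and tries < 500:
        tries += 1
        cy = rng.integers(radius_px, shape[0] - radius_px)
        cx = rng.integers(radius_px, shape[1] - radius_px)
        roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        if (roi & excluded).any():
            continue
        densities.append(neurite_length_density(scene, roi, channel, threshold))
    if not densities:
        raise RuntimeError("could not place any control ROI outside clusters")
    return float(np.median(densities))
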