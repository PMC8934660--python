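"""Microglial cluster detection with area/cell-count gates and ROI expansion.

Cells whose masks come within a proximity distance are merged into
candidate groups; a group is a cluster iff its union area exceeds the
minimum area AND it has at least the minimum number of member cells.
Accepted cluster cores are dilated by a border (20 um by default) to give
the region of interest scored for neurite damage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from gliastat.imaging.types import CellObject

__all__ = ["ClusterParams", "ClusterROI", "detect_clusters"]


@dataclass(frozen=True)
class ClusterParams:
    min_area_um2: float = 4000.0
    min_cells: int = 5
    border_um: float = 20.0
    proximity_um: float = 10.0

    def __post_init__(self):
        if min(self.min_area_um2, self.min_cells, self.border_um, self.proximity_um) <= 0:
            raise ValueError("all cluster parameters must be positive")


@dataclass
class ClusterROI:
    core_mask: np.ndarray  # union of member cell masks
    expanded_mask: np.ndarray  # core dilated by the border
    member_labels: tuple[int, ...]
    n_cells: int
    area_um2: float
    neurite_length_density: float | None = None
    damage_associated: bool | None = None


def _dilate(mask: np.ndarray, radius_px: int) -> np.ndarray:
    if radius_px < 1:
        return mask.copy()
    return ndi.binary_dilation(mask, structure=disk(radius_px))


def detect_clusters(
    cells: list[CellObject],
    pixel_size: float,
    params: ClusterParams = ClusterParams(),
) -> list[ClusterROI]:
    """Group proximal cells and apply the area and cell-count gates.

    Proximity is tested by dilating the union of cell masks by half the
    proximity distance and taking connected components, so two cells merge
    iff their masks are within `proximity_um` of each other.  The result is
    independent of cell ordering and idempotent.
    """
    if not cells:
        return []
    shape = cells[0].cell_mask.shape
    union = np.zeros(shape, dtype=bool)
    for c in cells:
        union |= c.cell_mask

    half_px = max(1, int(round(params.proximity_um / 2.0 / pixel_size)))
    groups, _ = ndi.label(_dilate(union, half_px))

    # map each cell to the group containing (the bulk of) its mask
    by_group: dict[int, list[CellObject]] = {}
    for c in cells:
        gids = groups[c.cell_mask]
        gid = int(np.bincount(gids[gids > 0]).argmax())
        by_group.setdefault(gid, []).append(c)

    border_px = max(1, int(round(params.border_um / pixel_size)))
    out: list[ClusterROI] = []
    for gid in sorted(by_group):
        members = by_group[gid]
        core = np.zeros(shape, dtype=bool)
        for c in members:
            core |= c.cell_mask
        area = float(core.sum()) * pixel_size**2
        if len(members) >= params.min_cells and area > params.min_area_um2:
            out.append(
                ClusterROI(
                    core_mask=core,
                    expanded_mask=_dilate(core, border_px),
                    member_labels=tuple(sorted(c.label for c in members)),
                    n_cells=len(members),
                    area_um2=area,
                )
            )
    return out
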