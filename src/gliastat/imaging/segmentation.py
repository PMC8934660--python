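"""Nucleus segmentation and secondary-object (cell) definition.

Nuclei are segmented from the DAPI channel by global thresholding, hole
filling, distance-transform watershed splitting of touching nuclei and a
minimum-size filter.  Cells are then grown from each nucleus into the
contiguous above-threshold pixels of a cytoplasmic channel (CFSE for
microglia); pixels reachable from two nuclei go to the nearer one.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from gliastat.imaging.types import CellObject, ImageScene
from gliastat.imaging.morphometrics import form_factor

logger = logging.getLogger(__name__)

__all__ = ["segment_nuclei", "define_cells"]


def segment_nuclei(
    scene: ImageScene,
    channel: str = "DAPI",
    threshold: float | None = None,
    min_area_um2: float = 10.0,
    split_min_distance_um: float = 4.0,
) -> np.ndarray:
    """Label image of nuclei from the DAPI channel.

    threshold=None uses global Otsu.  Touching nuclei are split by a
    watershed seeded at distance-transform peaks at least
    `split_min_distance_um` apart.  Returns an int label image (0 =
    background); a blank image yields zero nuclei with a warning.
    """
    img = scene.channel(channel)
    if img.max() == img.min():
        logger.warning("channel %s is constant; no nuclei segmented", channel)
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(img) if threshold is None else threshold
    mask = img > thr
    mask = ndi.binary_fill_holes(mask)
    min_px = max(1, int(round(min_area_um2 / scene.pixel_area)))
    mask = remove_small_objects(mask, max_size=min_px - 1)
    if not mask.any():
        logger.warning("no nuclei above threshold in channel %s", channel)
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(mask)
    min_dist_px = max(1, int(round(split_min_distance_um / scene.pixel_size)))
    peaks = peak_local_max(dist, min_distance=min_dist_px, labels=mask, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers=markers, mask=mask)
    labels = remove_small_objects(labels, max_size=min_px - 1)
    # relabel consecutively
    return np.searchsorted(np.unique(labels), labels).astype(np.int32)


def define_cells(
    nuclei: np.ndarray,
    scene: ImageScene,
    channel: str = "CFSE",
    threshold: float | None = None,
) -> list[CellObject]:
    """Grow one cell per nucleus into contiguous above-threshold pixels.

    Pixels contested by two nuclei are assigned to the geodesically nearer
    nucleus (watershed on the distance transform from nuclei).  A nucleus
    with no above-threshold surround yields a cell equal to its nucleus,
    flagged `no_growth`.
    """
    img = scene.channel(channel)
    if threshold is None:
        threshold = threshold_otsu(img) if img.max() > img.min() else np.inf
    grow_mask = (img > threshold) | (nuclei > 0)
    dist = ndi.distance_transform_edt(nuclei == 0)
    cell_labels = watershed(dist, markers=nuclei, mask=grow_mask)

    cells: list[CellObject] = []
    ps = scene.pixel_size
    for lab in np.unique(nuclei):
        if lab == 0:
            continue
        nmask = nuclei == lab
        cmask = cell_labels == lab
        cmask |= nmask  # nucleus always belongs to its cell
        no_growth = not (cmask & ~nmask).any()
        if no_growth:
            logger.info("nucleus %d has no above-threshold surround", lab)
        area = float(cmask.sum()) * scene.pixel_area
        perim = float(perimeter_crofton(cmask, directions=4)) * ps
        ff = form_factor(area, perim) if perim > 0 else float("nan")
        cells.append(
            CellObject(
                label=int(lab),
                nucleus_mask=nmask,
                cell_mask=cmask,
                area=area,
                perimeter=perim,
                form_factor=ff,
                no_growth=no_growth,
            )
        )
    return cells
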