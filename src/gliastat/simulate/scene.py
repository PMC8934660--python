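"""Synthetic fluorescence co-culture scenes with exact ground truth.

Renders a 2-D multi-channel scene of CFSE-labelled microglia on a
CTV-labelled neuronal network: DAPI nuclei, CFSE cell bodies (singles and
clusters), vinculin cytoplasm, RELB with configurable nuclear
translocation, a beta3-tubulin neurite network drawn as smooth random
spline curves of ~2 px width, and phagocytic-event marker spots.  Every
placed object — cell masks, cluster regions with area and member count,
damage flags, event marker states — is recorded exactly, so the imaging
stage can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import splev, splprep

from gliastat.imaging.events import PhagocyticEvent
from gliastat.imaging.types import ImageScene

__all__ = ["ClusterSpec", "SceneConfig", "TruthCluster", "GroundTruthScene", "render_coculture_scene"]

# rendering intensities (arbitrary fluorescence units)
_I_DAPI, _I_CFSE, _I_VINC, _I_RELB, _I_TUBB, _I_SPOT = 200.0, 120.0, 80.0, 60.0, 150.0, 100.0
_NUCLEUS_R_UM = 4.0
_SINGLE_R_UM = 9.0
_CLEARANCE_UM = 30.0  # min mask gap between placed objects


@dataclass(frozen=True)
class ClusterSpec:
    n_cells: int
    target_area_um2: float
    damaged: bool = False

    def __post_init__(self):
        if self.n_cells < 1 or self.target_area_um2 <= 0:
            raise ValueError("cluster needs >= 1 cell and positive area")


@dataclass(frozen=True)
class SceneConfig:
    image_size: int = 512
    pixel_size: float = 0.62  # um/px; 512 px ~ one 318x318 um field of view
    n_single_cells: int = 6
    clusters: tuple[ClusterSpec, ...] = ()
    neurite_curves_per_mm2: float = 700.0
    damage_fraction_in_clusters: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0
    translocated_fraction: float = 0.4
    nuclear_cyto_ratio: float = 3.0  # nuclear:cytoplasmic RELB in translocated cells
    nuclear_cyto_ratio_resting: float = 0.5  # cytoplasm-sequestered in resting cells
    n_phagocytic_events: int = 20

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.damage_fraction_in_clusters <= 1.0:
            raise ValueError("damage_fraction_in_clusters must be in [0, 1]")
        fov = self.image_size * self.pixel_size
        for c in self.clusters:
            radius = np.sqrt(c.target_area_um2 / np.pi)
            if 2 * (radius + _CLEARANCE_UM) >= fov:
                raise ValueError(
                    f"cluster of {c.target_area_um2} um^2 does not fit a {fov:.0f} um field"
                )


@dataclass
class TruthCluster:
    mask: np.ndarray
    n_cells: int
    is_damaged: bool
    area_um2: float
    member_labels: tuple[int, ...]


@dataclass
class GroundTruthScene:
    channels: dict[str, np.ndarray]
    pixel_size: float
    label_masks: dict[str, np.ndarray]  # nuclei, microglia (int); neurites, neurites_intact (bool)
    truth_clusters: list[TruthCluster]
    truth_events: list[PhagocyticEvent]
    truth_translocated: dict[int, bool]
    config: SceneConfig

    @property
    def scene(self) -> ImageScene:
        return ImageScene(channels=self.channels, pixel_size=self.pixel_size)


def _disk_mask(shape, cy, cx, r_px) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2


def _place(rng, placed, r_um, fov, margin_um, max_tries=4000):
    """Random centre (um) at least clearance away from everything placed."""
    for _ in range(max_tries):
        cy = rng.uniform(margin_um, fov - margin_um)
        cx = rng.uniform(margin_um, fov - margin_um)
        ok = all(
            np.hypot(cy - py, cx - px) > r_um + pr + _CLEARANCE_UM for py, px, pr in placed
        )
        if ok:
            placed.append((cy, cx, r_um))
            return cy, cx
    raise ValueError("could not place all objects; scene too crowded")


def _spline_curve(rng, fov, n_ctrl=5, step_um=80.0):
    """Smooth random curve through a jittered random walk of control points."""
    pts = [rng.uniform(0, fov, size=2)]
    ang = rng.uniform(0, 2 * np.pi)
    for _ in range(n_ctrl - 1):
        ang += rng.normal(0, 0.9)
        pts.append(pts[-1] + step_um * np.array([np.sin(ang), np.cos(ang)]))
    pts = np.array(pts).T
    try:
        tck, _ = splprep(pts, s=0.0, k=min(3, pts.shape[1] - 1))
    except Exception:
        return None
    t = np.linspace(0, 1, 400)
    return np.array(splev(t, tck)).T  # (400, 2) in um


def render_coculture_scene(config: SceneConfig) -> GroundTruthScene:
    """Render the scene described by `config`; deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_px = config.image_size
    ps = config.pixel_size
    fov = n_px * ps
    shape = (n_px, n_px)

    channels = {
        name: np.zeros(shape) for name in ("DAPI", "CFSE", "CTV", "TUBB3", "caspase3", "vinculin", "RELB")
    }
    nuclei_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)

    placed: list[tuple[float, float, float]] = []
    label = 0
    truth_clusters: list[TruthCluster] = []
    nucleus_r_px = max(2, int(round(_NUCLEUS_R_UM / ps)))

    # --- clusters first (largest objects) ---
    for spec in config.clusters:
        r_um = np.sqrt(spec.target_area_um2 / np.pi)
        cy, cx = _place(rng, placed, r_um, fov, margin_um=r_um + _CLEARANCE_UM)
        region = _disk_mask(shape, cy / ps, cx / ps, r_um / ps)

        # nuclei spread inside the region, pairwise separated
        centres: list[tuple[float, float]] = []
        tries = 0
        while len(centres) < spec.n_cells and tries < 20000:
            tries += 1
            rr = (r_um - _NUCLEUS_R_UM - 2.0) * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            ny, nx = cy + rr * np.sin(th), cx + rr * np.cos(th)
            if all(np.hypot(ny - oy, nx - ox) > 2.5 * _NUCLEUS_R_UM for oy, ox in centres):
                centres.append((ny, nx))
        if len(centres) < spec.n_cells:
            raise ValueError(f"could not fit {spec.n_cells} nuclei in a cluster of {spec.target_area_um2} um^2")

        member_labels = []
        seeds = np.zeros(shape, dtype=np.int32)
        for ny, nx in centres:
            label += 1
            member_labels.append(label)
            nmask = _disk_mask(shape, ny / ps, nx / ps, nucleus_r_px)
            nuclei_labels[nmask] = label
            seeds[int(round(ny / ps)), int(round(nx / ps))] = label
        # partition the cluster region among member nuclei (nearest seed)
        dist, (iy, ix) = ndi.distance_transform_edt(seeds == 0, return_indices=True)
        nearest = seeds[iy, ix]
        cell_labels[region] = nearest[region]

        truth_clusters.append(
            TruthCluster(
                mask=region,
                n_cells=spec.n_cells,
                is_damaged=spec.damaged and config.damage_fraction_in_clusters > 0,
                area_um2=float(region.sum()) * ps**2,
                member_labels=tuple(member_labels),
            )
        )

    # --- isolated single cells ---
    for _ in range(config.n_single_cells):
        cy, cx = _place(rng, placed, _SINGLE_R_UM, fov, margin_um=_SINGLE_R_UM + _CLEARANCE_UM)
        label += 1
        body = _disk_mask(shape, cy / ps, cx / ps, _SINGLE_R_UM / ps)
        nmask = _disk_mask(shape, cy / ps, cx / ps, nucleus_r_px)
        nuclei_labels[nmask] = label
        cell_labels[body] = label

    # --- paint cell channels ---
    microglia = cell_labels > 0
    channels["DAPI"][nuclei_labels > 0] = _I_DAPI
    channels["CFSE"][microglia] = _I_CFSE
    channels["vinculin"][microglia] = _I_VINC

    labels = list(range(1, label + 1))
    n_transloc = int(round(config.translocated_fraction * len(labels)))
    transloc = set(rng.choice(labels, size=n_transloc, replace=False)) if n_transloc else set()
    truth_translocated = {}
    for lab in labels:
        cmask = cell_labels == lab
        nmask = nuclei_labels == lab
        channels["RELB"][cmask & ~nmask] = _I_RELB
        is_t = lab in transloc
        ratio = config.nuclear_cyto_ratio if is_t else config.nuclear_cyto_ratio_resting
        channels["RELB"][nmask] = _I_RELB * ratio
        truth_translocated[lab] = is_t

    # --- neurite network ---
    area_mm2 = (fov / 1000.0) ** 2
    n_curves = int(round(config.neurite_curves_per_mm2 * area_mm2))
    neurites = np.zeros(shape, dtype=bool)
    for _ in range(n_curves):
        curve = _spline_curve(rng, fov)
        if curve is None:
            continue
        px = np.round(curve / ps).astype(int)
        ok = (px[:, 0] >= 0) & (px[:, 0] < n_px) & (px[:, 1] >= 0) & (px[:, 1] < n_px)
        neurites[px[ok, 0], px[ok, 1]] = True
    neurites = ndi.binary_dilation(neurites)  # ~2 px width
    neurites_intact = neurites.copy()

    # --- erase neurite signal inside damaged cluster ROIs ---
    frac = config.damage_fraction_in_clusters
    border_px = max(1, int(round(20.0 / ps)))
    for tc in truth_clusters:
        if not tc.is_damaged:
            continue
        roi = ndi.binary_dilation(tc.mask, iterations=border_px)
        inside = np.argwhere(neurites & roi)
        n_erase = int(round(frac * len(inside)))
        if n_erase:
            pick = inside[rng.choice(len(inside), size=n_erase, replace=False)]
            neurites[pick[:, 0], pick[:, 1]] = False
    channels["TUBB3"][neurites] = _I_TUBB

    # --- phagocytic-event spots ---
    truth_events: list[PhagocyticEvent] = []
    spot_r = 2
    for _ in range(config.n_phagocytic_events):
        ey, ex = rng.integers(spot_r, n_px - spot_r, size=2)
        tubb3 = bool(rng.uniform() < 0.8)
        ev = PhagocyticEvent(
            location=(float(ey * ps), float(ex * ps)),
            ctv=True,
            caspase3=bool(rng.uniform() < 0.4),
            tubb3=tubb3,
            dapi=bool(tubb3 and rng.uniform() < 0.5),
        )
        truth_events.append(ev)
        spot = _disk_mask(shape, ey, ex, spot_r)
        channels["CTV"][spot] = np.maximum(channels["CTV"][spot], _I_SPOT)
        if ev.caspase3:
            channels["caspase3"][spot] = np.maximum(channels["caspase3"][spot], _I_SPOT)

    if config.noise_sd > 0:
        for name in channels:
            channels[name] = np.maximum(
                channels[name] + rng.normal(0.0, config.noise_sd, size=shape), 0.0
            )

    return GroundTruthScene(
        channels=channels,
        pixel_size=ps,
        label_masks={
            "nuclei": nuclei_labels,
            "microglia": cell_labels,
            "neurites": neurites,
            "neurites_intact": neurites_intact,
        },
        truth_clusters=truth_clusters,
        truth_events=truth_events,
        truth_translocated=truth_translocated,
        config=config,
    )
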