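"""Core imaging containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageScene", "CellObject"]


@dataclass
class ImageScene:
    """Multi-channel 2-D fluorescence scene.

    channels: name -> 2-D float image (all same shape); pixel_size in
    micrometres per pixel; background holds optional per-channel scalar
    levels from a secondary-antibody-only control, subtracted before any
    intensity quantification.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    background: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {ch: img.shape for ch, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in square micrometres."""
        return self.pixel_size**2

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in scene (have {sorted(self.channels)})")
        return self.channels[name]

    def background_subtracted(self, name: str) -> np.ndarray:
        """Channel minus its background control level, floored at 0."""
        return np.maximum(self.channel(name) - self.background.get(name, 0.0), 0.0)


@dataclass
class CellObject:
    """One segmented cell: a nucleus and the cell mask grown from it."""

    label: int
    nucleus_mask: np.ndarray  # bool
    cell_mask: np.ndarray  # bool, superset of nucleus_mask
    area: float  # um^2
    perimeter: float  # um
    form_factor: float
    no_growth: bool = False  # no above-threshold surround; cell == nucleus

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nucleus_mask
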