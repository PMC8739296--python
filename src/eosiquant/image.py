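"""Single-channel image container shared by all image operators."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


@dataclass
class IntensityImage:
    """A 2-D single-channel raster with optional physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite intensities.  Dtype is preserved where it
        matters (the 8-bit stage of the CARS chain tags itself ``"8-bit"``).
    pixel_size : float, optional
        Physical edge length of one pixel in micrometres.  Required by
        operators whose gates are expressed in µm² (fluorescence module).
    bit_depth : str
        ``"native"`` for arbitrary-range data, ``"8-bit"`` once an image has
        been quantized to the 0–255 integer range.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None
    bit_depth: str = "native"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("IntensityImage requires a 2-D array of size >= 1x1")
        if not np.all(np.isfinite(self.pixels.astype(float, copy=False))):
            raise ValueError("IntensityImage pixels must be finite")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm/px)")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, bit_depth: Optional[str] = None) -> "IntensityImage":
        """Return a copy carrying new pixel data but the same metadata."""
        return replace(
            self,
            pixels=pixels,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
            meta=dict(self.meta),
        )

    def area_px(self, area_um2: float) -> float:
        """Convert an area in µm² to pixels² using the pixel-size metadata."""
        if self.pixel_size is None:
            raise ValueError("pixel_size metadata is required for µm²-based gates")
        return area_um2 / (self.pixel_size**2)
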