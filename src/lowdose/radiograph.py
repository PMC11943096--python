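"""The in-memory radiograph container shared by all modules.

A projection radiograph here is a 2-D integer grey-value image (8- or
16-bit) plus optional acquisition metadata.  The package-wide polarity
convention is *standard* = grey value 0 corresponds to direct exposure
(unattenuated beam hitting the detector) and higher grey values to more
attenuation.  Images flagged ``photometric="inverted"`` (air bright, as in
DICOM MONOCHROME1 display convention) are flipped to the standard
convention before noise simulation and flipped back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Radiograph"]


@dataclass
class Radiograph:
    """A 2-D grey-value image with acquisition metadata.

    Parameters
    ----------
    pixels
        2-D integer array, values in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.
    photometric
        ``"standard"`` (grey 0 = direct exposure) or ``"inverted"``.
    meta
        Optional acquisition metadata.  Keys used elsewhere in the
        package: ``kvp`` (tube voltage, kilovolts peak), ``mas``
        (exposure time product, milliampere-seconds), ``view`` (PA/AP),
        ``gender`` (M/F), ``acquisition_date``, ``anchor_age``,
        ``anchor_year``, ``patient_id``.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    photometric: str = "standard"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.photometric not in ("standard", "inverted"):
            raise ValueError(f"unknown photometric {self.photometric!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def peak(self) -> int:
        """Maximum representable grey value, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def dtype_for_depth(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    def with_pixels(self, pixels: np.ndarray, **meta_updates: Any) -> "Radiograph":
        """Copy carrying new pixel data and (optionally) extra metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Radiograph(pixels, self.bit_depth, self.photometric, meta)
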