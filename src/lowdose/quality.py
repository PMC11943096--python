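"""Objective image-quality verification of low-dose simulations.

PSNR and SSIM compare each simulation against its originating image, at
full resolution and at the two classifier input resolutions: LR
(254 x 305 px) and ULR (127 x 152 px).  Because downscaling averages
away high-frequency noise, PSNR rises as resolution falls — the same
simulation looks progressively more like its original at LR and ULR.
The report quantifies exactly that resolution-dependence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .calibration import NoiseCalibration
from .ingen import SimulationConfig, simulate_low_dose
from .radiograph import Radiograph

__all__ = [
    "RESOLUTION_DIMS",
    "QualityReport",
    "psnr",
    "ssim",
    "downscale",
    "quality_report",
]

logger = logging.getLogger(__name__)

#: Named classifier input resolutions, (rows, cols).
RESOLUTION_DIMS: dict[str, tuple[int, int]] = {
    "LR": (254, 305),
    "ULR": (127, 152),
}


def psnr(reference: Radiograph, test: Radiograph) -> float:
    """Peak signal-to-noise ratio in decibels.

    ``10 * log10(peak^2 / MSE)`` with peak the bit-depth maximum
    (``2**bit_depth - 1``), not the observed image maximum.  Identical
    images return ``math.inf``.
    """
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if reference.bit_depth != test.bit_depth:
        raise ValueError(
            f"bit depth mismatch: {reference.bit_depth} vs {test.bit_depth}"
        )
    diff = reference.as_float() - test.as_float()
    mse = float(np.mean(diff * diff))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(reference.peak**2 / mse)


def ssim(reference: Radiograph, test: Radiograph) -> float:
    """Single-scale structural similarity (7x7 windows, bit-depth range)."""
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    return float(
        structural_similarity(
            reference.as_float(), test.as_float(), data_range=float(reference.peak)
        )
    )


def downscale(
    image: Radiograph, target: str | tuple[int, int]
) -> Radiograph:
    """Anti-aliased downscale to a named (LR/ULR) or explicit size.

    Upscaling requests are rejected; a matching-size request returns
    the image unchanged (idempotence).
    """
    if isinstance(target, str):
        try:
            dims = RESOLUTION_DIMS[target]
        except KeyError:
            raise ValueError(
                f"unknown resolution label {target!r}; known: {sorted(RESOLUTION_DIMS)}"
            ) from None
    else:
        dims = (int(target[0]), int(target[1]))
    if dims == image.shape:
        return image.with_pixels(image.pixels.copy())
    if dims[0] > image.shape[0] or dims[1] > image.shape[1]:
        raise ValueError(f"cannot upscale {image.shape} to {dims}")
    arr = resize(
        image.as_float(), dims, anti_aliasing=True, preserve_range=True, order=1
    )
    out = np.clip(np.rint(arr), 0, image.peak).astype(image.dtype_for_depth())
    return image.with_pixels(out)


@dataclass
class QualityReport:
    """Mean +/- SD PSNR and SSIM per (dose fraction, resolution)."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def row(self, dose_fraction: float, resolution_label: str) -> dict:
        for r in self.rows:
            if (
                r["dose_fraction"] == dose_fraction
                and r["resolution_label"] == resolution_label
            ):
                return r
        raise KeyError((dose_fraction, resolution_label))


def quality_report(
    originals: Sequence[Radiograph],
    cal: NoiseCalibration,
    dose_fractions: Sequence[float],
    config: SimulationConfig = SimulationConfig(),
    resolutions: Sequence[str] = ("original", "LR", "ULR"),
) -> QualityReport:
    """Simulate each dose level and score it at each resolution.

    For LR/ULR both the original and the simulation are downscaled
    before comparison; a named resolution the images cannot be reduced
    to (input smaller than the target) is skipped with a warning.  Per
    image the simulation seed is offset by the image index so replicate
    images receive independent noise.
    """
    if len(originals) == 0:
        raise ValueError("at least one original image is required")
    min_dims = (
        min(o.shape[0] for o in originals),
        min(o.shape[1] for o in originals),
    )
    usable = []
    for label in resolutions:
        dims = RESOLUTION_DIMS.get(label)
        if dims is not None and (dims[0] > min_dims[0] or dims[1] > min_dims[1]):
            logger.warning(
                "skipping resolution %s %s: images are only %s", label, dims, min_dims
            )
            continue
        usable.append(label)
    resolutions = usable
    report = QualityReport()
    for dose in dose_fractions:
        sims = []
        for i, orig in enumerate(originals):
            cfg = SimulationConfig(
                **{
                    **config.__dict__,
                    "dose_fraction": dose,
                    "seed": config.seed + i,
                }
            )
            sims.append(simulate_low_dose(orig, cal, cfg))
        for label in resolutions:
            psnrs, ssims = [], []
            for orig, sim in zip(originals, sims):
                if label == "original":
                    a, b = orig, sim
                else:
                    a, b = downscale(orig, label), downscale(sim, label)
                psnrs.append(psnr(a, b))
                ssims.append(ssim(a, b))
            report.rows.append(
                {
                    "resolution_label": label,
                    "dose_fraction": dose,
                    "psnr_db_mean": float(np.mean(psnrs)),
                    "psnr_db_sd": float(np.std(psnrs, ddof=1)) if len(psnrs) > 1 else 0.0,
                    "ssim_mean": float(np.mean(ssims)),
                    "ssim_sd": float(np.std(ssims, ddof=1)) if len(ssims) > 1 else 0.0,
                    "n_images": len(originals),
                }
            )
    return report
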