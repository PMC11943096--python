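"""Signal-dependent noise calibration from phantom radiographs.

In projection radiography the local noise standard deviation grows with
the local mean grey value: regions behind dense anatomy (high
attenuation, high grey value under this package's polarity convention)
receive fewer quanta and are noisier.  The calibration procedure
quantifies this with sliding-window statistics: the image is covered
with small square windows (10 x 10 px by default), the sample mean and
sample SD of each window are collected, and SD is regressed on mean with
a straight line forced through the origin.  The through-origin form
absorbs the direct-exposure background, where grey values are 0 and the
SD is negligible, without letting it bias an intercept.

The fitted slope (SD per unit mean grey value) characterises one
acquisition setting (kVp, mAs).  A grid of phantom acquisitions — e.g.
3 tube voltages x 5 exposure products — yields a :class:`NoiseCalibration`
table.  The slope of a lower-mAs acquisition serves as the *goal slope*
when simulating a dose reduction from a full-dose image: halving the
dose (mAs) raises the slope by roughly sqrt(2), since quantum noise
scales as 1/sqrt(dose).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .radiograph import Radiograph

__all__ = [
    "WindowStat",
    "CalibrationEntry",
    "NoiseCalibration",
    "window_statistics",
    "fit_noise_slope",
    "measured_noise_slope",
    "build_calibration",
    "goal_slope",
    "load_window_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 10
DEFAULT_STRIDE = 10
#: Minimum number of windows for a calibration entry to be considered solid.
MIN_WINDOWS = 30


@dataclass(frozen=True)
class WindowStat:
    """Sample statistics of one analysis window.

    ``row``/``col`` are the pixel indices of the window's top-left
    corner; ``mean_grey``/``sd_grey`` are the sample mean and sample SD
    (ddof=1) of the window's pixels.
    """

    row: int
    col: int
    mean_grey: float
    sd_grey: float


@dataclass(frozen=True)
class CalibrationEntry:
    kvp: float
    mas: float
    slope: float
    n_windows: int
    r_squared: float


@dataclass
class NoiseCalibration:
    """Noise slope per (kVp, mAs) acquisition setting.

    Records the window size and stride used, so downstream measurements
    (e.g. the auto-factor loop in :mod:`lowdose.ingen`) can match them.
    """

    entries: list[CalibrationEntry] = field(default_factory=list)
    window_size: int = DEFAULT_WINDOW_SIZE
    stride: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        keys = [(e.kvp, e.mas) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (kvp, mas) entries in calibration")

    def kvps(self) -> list[float]:
        return sorted({e.kvp for e in self.entries})

    def entries_at(self, kvp: float) -> list[CalibrationEntry]:
        """Entries at the requested kVp, sorted by mAs ascending.

        A kVp absent from the table falls back to the nearest available
        one (with a warning): clinical requests rarely hit the phantom
        grid exactly, e.g. a fleet-average 101 kVp against an 80/100/120
        phantom series.
        """
        if not self.entries:
            raise ValueError("calibration is empty")
        available = self.kvps()
        if kvp not in available:
            nearest = min(available, key=lambda v: (abs(v - kvp), v))
            logger.warning("no calibration at %g kVp; using nearest %g kVp", kvp, nearest)
            kvp = nearest
        return sorted((e for e in self.entries if e.kvp == kvp), key=lambda e: e.mas)

    # -- persistence -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "window_size": self.window_size,
            "stride": self.stride,
            "entries": [asdict(e) for e in self.entries],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NoiseCalibration":
        doc = json.loads(text)
        entries = [CalibrationEntry(**e) for e in doc["entries"]]
        return cls(entries, doc["window_size"], doc["stride"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "NoiseCalibration":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

def _pixels_of(image: Radiograph | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, Radiograph) else np.asarray(image)
    return arr.astype(np.float64, copy=False)


def _window_stat_arrays(
    arr: np.ndarray, window_size: int, stride: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    h, w = arr.shape
    if h < window_size or w < window_size:
        raise ValueError(
            f"image of size {h}x{w} is smaller than the {window_size}x{window_size} window"
        )
    view = sliding_window_view(arr, (window_size, window_size))[::stride, ::stride]
    means = view.mean(axis=(-2, -1))
    sds = view.std(axis=(-2, -1), ddof=1)
    rows = np.arange(view.shape[0]) * stride
    cols = np.arange(view.shape[1]) * stride
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return rr.ravel(), cc.ravel(), means.ravel(), sds.ravel()


def window_statistics(
    image: Radiograph | np.ndarray,
    window_size: int = DEFAULT_WINDOW_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> list[WindowStat]:
    """Mean/SD of every complete window position.

    Windows that would overhang the image edge are dropped.  The default
    stride equals the window size (non-overlapping tiling); ``stride=1``
    gives fully overlapping sliding windows at higher cost — the fitted
    slope's expectation is the same either way.
    """
    arr = _pixels_of(image)
    rows, cols, means, sds = _window_stat_arrays(arr, window_size, stride)
    return [
        WindowStat(int(r), int(c), float(m), float(s))
        for r, c, m, s in zip(rows, cols, means, sds)
    ]


# ---------------------------------------------------------------------------
# through-origin regression
# ---------------------------------------------------------------------------

def _fit_arrays(means: np.ndarray, sds: np.ndarray) -> tuple[float, float]:
    denom = float(np.sum(means * means))
    if denom == 0.0:
        raise ValueError("through-origin regression undefined: all window means are zero")
    slope = max(float(np.sum(means * sds)) / denom, 0.0)
    ss_tot = float(np.sum(sds * sds))
    if ss_tot == 0.0:
        r_squared = 1.0
    else:
        ss_res = float(np.sum((sds - slope * means) ** 2))
        r_squared = 1.0 - ss_res / ss_tot
    return slope, r_squared


def fit_noise_slope(stats: Sequence[WindowStat]) -> tuple[float, float]:
    """Least-squares slope of SD on mean, forced through the origin.

    ``slope = sum(mean * sd) / sum(mean**2)``, with R^2 for the
    uncentred (through-origin) model.  Background windows (mean 0)
    contribute nothing but are accepted — forcing the intercept exists
    precisely to neutralise them.
    """
    if len(stats) == 0:
        raise ValueError("no window statistics supplied")
    means = np.array([s.mean_grey for s in stats], dtype=np.float64)
    sds = np.array([s.sd_grey for s in stats], dtype=np.float64)
    return _fit_arrays(means, sds)


def measured_noise_slope(
    image: Radiograph | np.ndarray,
    window_size: int = DEFAULT_WINDOW_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> float:
    """Fitted noise slope of a single image (fast array path)."""
    arr = _pixels_of(image)
    _, _, means, sds = _window_stat_arrays(arr, window_size, stride)
    slope, _ = _fit_arrays(means, sds)
    return slope


# ---------------------------------------------------------------------------
# calibration table
# ---------------------------------------------------------------------------

def build_calibration(
    images: Iterable[Radiograph],
    window_size: int = DEFAULT_WINDOW_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> NoiseCalibration:
    """Fit one noise slope per (kVp, mAs) setting.

    Images sharing an acquisition setting are pooled (their window
    statistics concatenated) before fitting, so replicate acquisitions
    sharpen rather than duplicate an entry.
    """
    groups: dict[tuple[float, float], list[tuple[np.ndarray, np.ndarray]]] = {}
    n_images = 0
    for i, img in enumerate(images):
        n_images += 1
        kvp = img.meta.get("kvp")
        mas = img.meta.get("mas")
        if kvp is None or mas is None:
            raise ValueError(
                f"image #{i} is missing kvp/mas metadata (got kvp={kvp!r}, mas={mas!r})"
            )
        _, _, means, sds = _window_stat_arrays(_pixels_of(img), window_size, stride)
        groups.setdefault((float(kvp), float(mas)), []).append((means, sds))
    if n_images == 0:
        raise ValueError("no calibration images supplied")

    entries = []
    for (kvp, mas), stat_pairs in sorted(groups.items()):
        means = np.concatenate([m for m, _ in stat_pairs])
        sds = np.concatenate([s for _, s in stat_pairs])
        slope, r_squared = _fit_arrays(means, sds)
        n_windows = int(means.size)
        if n_windows < MIN_WINDOWS:
            logger.warning(
                "calibration entry (%g kVp, %g mAs) rests on only %d windows", kvp, mas, n_windows
            )
        entries.append(CalibrationEntry(kvp, mas, slope, n_windows, r_squared))
    return NoiseCalibration(entries, window_size, stride)


def goal_slope(
    cal: NoiseCalibration,
    kvp: float,
    reference_mas: float,
    dose_fraction: float,
    mode: str = "nearest",
) -> float:
    """Target noise slope for a simulated dose reduction.

    The target exposure is ``reference_mas * dose_fraction``; the
    returned slope is that of the calibration entry at the requested kVp
    whose mAs lies nearest the target (``mode="nearest"``, ties broken
    toward the lower, noisier mAs), or a log-linear interpolation in mAs
    between the bracketing entries (``mode="interp"``, clamped at the
    table ends).
    """
    if not 0.0 < dose_fraction <= 1.0:
        raise ValueError(f"dose_fraction must be in (0, 1], got {dose_fraction}")
    if reference_mas <= 0:
        raise ValueError(f"reference_mas must be positive, got {reference_mas}")
    candidates = cal.entries_at(kvp)  # raises on empty calibration
    target = reference_mas * dose_fraction
    if mode == "nearest":
        best = min(candidates, key=lambda e: (abs(e.mas - target), e.mas))
        return best.slope
    if mode == "interp":
        if target <= candidates[0].mas:
            return candidates[0].slope
        if target >= candidates[-1].mas:
            return candidates[-1].slope
        for lo, hi in zip(candidates, candidates[1:]):
            if lo.mas <= target <= hi.mas:
                t = (math.log(target) - math.log(lo.mas)) / (
                    math.log(hi.mas) - math.log(lo.mas)
                )
                return lo.slope + t * (hi.slope - lo.slope)
        raise AssertionError("unreachable: target not bracketed")  # pragma: no cover
    raise ValueError(f"unknown goal-slope mode {mode!r}")


def load_window_csv(path: str | Path) -> list[WindowStat]:
    """Load window statistics from a two-column (mean, sd) CSV file.

    Accepts files with or without a header line; row/col positions are
    not part of this dialect and are filled with -1.
    """
    import pandas as pd

    df = pd.read_csv(path, header=None)
    try:
        df = df.astype(float)
    except (ValueError, TypeError):
        df = pd.read_csv(path).iloc[:, :2].astype(float)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (mean, sd), got {df.shape[1]}")
    return [
        WindowStat(-1, -1, float(m), float(s))
        for m, s in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]
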