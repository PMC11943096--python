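"""Synthetic phantom radiographs, cohorts and paired classifier scores.

Every downstream module — calibration, noise simulation, quality
verification, curation, evaluation — is exercised against data from
this module, so no external image archive is needed.

The phantom emulates an anthropomorphic chest phantom only in the one
property that matters for noise calibration: a known signal-dependent
noise law.  The noise-free signal field is a set of flat, anatomy-like
plateaus (background at grey 0 = direct exposure, lung-, soft-tissue-,
heart- and bone-like levels) and the observed image adds zero-mean
Gaussian noise with per-pixel standard deviation ``k * S`` where
``k = noise_coeff / sqrt(mas)`` — the 1/sqrt(dose) scaling of quantum
noise.  Plateau edges are sharp and snapped to a 20-px grid so that the
default 10-px analysis tiling never straddles an edge; sliding-window
regression on such an image recovers ``k`` to within a few percent at
512^2 px, which is the end-to-end oracle for the calibration module.

Cohort and score generators emulate, respectively, MIMIC-CXR-JPG-style
label tables (values 1/0/-1 per pathology) and paired classifier scores
under the binormal model, where a positive-class mean shift of
``mu = sqrt(2) * Phi^-1(AUC)`` with unit variances yields a chosen true
AUROC.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .curation import INCLUDED_PATHOLOGIES, LabelRecord
from .evaluation import DOSE_CONDITIONS, PredictionSet
from .radiograph import Radiograph

__all__ = [
    "SyntheticPhantomSpec",
    "SyntheticCohortSpec",
    "REGION_LEVELS",
    "signal_field",
    "generate_phantom",
    "generate_cohort",
    "generate_paired_scores",
    "generate_prediction_set",
]

#: Region attenuation levels as fractions of the dynamic range.  Grey 0 is
#: direct exposure; bone attenuates most.  Max level 0.62 keeps clipping
#: negligible at default noise levels while spanning >50% of the range.
REGION_LEVELS: dict[str, float] = {
    "background": 0.00,
    "lung": 0.18,
    "soft_tissue": 0.30,
    "heart": 0.42,
    "bone": 0.62,
}
_REGION_CODES = {name: i for i, name in enumerate(REGION_LEVELS)}

#: Plateau edges are snapped to this grid so the default 10-px window
#: tiling sees pure plateaus only.
_EDGE_GRID = 20


@dataclass(frozen=True)
class SyntheticPhantomSpec:
    """Acquisition settings for one synthetic phantom exposure."""

    height: int = 512
    width: int = 512
    kvp: float = 100.0
    mas: float = 2.0
    noise_coeff: float = 0.007  # c in slope k = c / sqrt(mas); SNR ~ 200 at 2 mAs
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError(
                f"phantom must be at least 64x64 px, got {self.height}x{self.width}"
            )
        if self.mas <= 0:
            raise ValueError(f"mas must be positive, got {self.mas}")
        if self.noise_coeff < 0:
            raise ValueError(f"noise_coeff must be >= 0, got {self.noise_coeff}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def noise_slope(self) -> float:
        """The true SD-per-unit-mean slope, ``noise_coeff / sqrt(mas)``."""
        return self.noise_coeff / math.sqrt(self.mas)


def _snap(x: float) -> int:
    return int(round(x / _EDGE_GRID)) * _EDGE_GRID


def signal_field(spec: SyntheticPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free signal and region-label map for a phantom spec.

    Returns ``(S, labels)`` where ``S`` is the float signal field and
    ``labels`` codes regions per :data:`REGION_LEVELS` order.
    """
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.uint8)

    def box(rf0: float, rf1: float, cf0: float, cf1: float, region: str) -> None:
        r0, r1 = max(_snap(rf0 * h), 0), min(_snap(rf1 * h), h)
        c0, c1 = max(_snap(cf0 * w), 0), min(_snap(cf1 * w), w)
        labels[r0:r1, c0:c1] = _REGION_CODES[region]

    box(0.06, 0.94, 0.12, 0.88, "soft_tissue")  # torso
    box(0.10, 0.55, 0.16, 0.42, "lung")         # right lung field
    box(0.10, 0.55, 0.58, 0.84, "lung")         # left lung field
    box(0.55, 0.86, 0.30, 0.70, "heart")        # cardiac silhouette
    box(0.06, 0.94, 0.44, 0.56, "bone")         # spine column

    peak = (1 << spec.bit_depth) - 1
    levels = np.array(
        [round(f * peak) for f in REGION_LEVELS.values()], dtype=np.float64
    )
    return levels[labels], labels


def generate_phantom(spec: SyntheticPhantomSpec) -> Radiograph:
    """Render one phantom exposure under the signal-proportional noise law.

    Pixel values are ``S + N(0, 1) * k * S`` with ``k = noise_coeff /
    sqrt(mas)``, rounded and clipped to the bit depth.  The background
    (grey 0) stays exactly 0, mirroring direct-exposure regions whose SD
    is negligible.  Bit-identical for equal spec (the seed is part of
    the spec).
    """
    S, _ = signal_field(spec)
    peak = (1 << spec.bit_depth) - 1
    k = spec.noise_slope
    if k == 0.0:
        img = S
    else:
        rng = np.random.default_rng(spec.seed)
        img = np.clip(np.rint(S + rng.standard_normal(S.shape) * (k * S)), 0, peak)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return Radiograph(
        img.astype(dtype),
        bit_depth=spec.bit_depth,
        photometric="standard",
        meta={
            "kvp": spec.kvp,
            "mas": spec.mas,
            "noise_coeff": spec.noise_coeff,
            "seed": spec.seed,
            "source": "synthetic-phantom",
        },
    )


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Shape of a synthetic label table.

    ``prevalence`` may be a single fraction applied to every pathology
    or a per-pathology mapping.  Uncertainty is resolved first: a label
    is -1 with probability ``uncertain_rate`` and otherwise 1 with the
    pathology's prevalence.  ``support_device_rate`` is the fraction of
    studies positively labelled under Support Devices (the curation
    exclusion rule needs positives to bite on).
    """

    n_records: int = 1000
    pathologies: tuple[str, ...] = INCLUDED_PATHOLOGIES
    prevalence: float | Mapping[str, float] = 0.5
    uncertain_rate: float = 0.02
    support_device_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        prevs = (
            self.prevalence.values()
            if isinstance(self.prevalence, Mapping)
            else [self.prevalence]
        )
        if any(not 0.0 <= p <= 1.0 for p in prevs):
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if not 0.0 <= self.uncertain_rate <= 1.0:
            raise ValueError(f"uncertain_rate must lie in [0, 1], got {self.uncertain_rate}")

    def prevalence_of(self, pathology: str) -> float:
        if isinstance(self.prevalence, Mapping):
            return float(self.prevalence[pathology])
        return float(self.prevalence)


def generate_cohort(spec: SyntheticCohortSpec) -> list[LabelRecord]:
    """Draw a synthetic label table; deterministic given the spec's seed.

    Views are drawn 60/40 PA/AP and genders 50/50; anchor ages are
    uniform on 18..90 years and anchor years on the de-identified
    2110..2200 band, with acquisitions 0-3 years after the anchor.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_records):
        labels: dict[str, int] = {}
        for p in spec.pathologies:
            if rng.random() < spec.uncertain_rate:
                labels[p] = -1
            else:
                labels[p] = int(rng.random() < spec.prevalence_of(p))
        support = int(rng.random() < spec.support_device_rate)
        anchor_year = int(rng.integers(2110, 2201))
        acq_year = anchor_year + int(rng.integers(0, 4))
        acq = _dt.date(acq_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        records.append(
            LabelRecord(
                study_id=f"s{i:07d}",
                patient_id=f"p{i // 2:07d}",
                labels=labels,
                support_devices=support,
                gender="M" if rng.random() < 0.5 else "F",
                view="PA" if rng.random() < 0.6 else "AP",
                anchor_age=float(rng.integers(18, 91)),
                anchor_year=anchor_year,
                acquisition_date=acq,
            )
        )
    return records


# ---------------------------------------------------------------------------
# paired classifier scores
# ---------------------------------------------------------------------------

def generate_paired_scores(
    n_pos: int,
    n_neg: int,
    target_auc: float,
    perturbation_sd: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binormal scores plus a paired, perturbed copy.

    ``scores_a`` follows the equal-variance binormal model with
    positive-class mean ``mu = sqrt(2) * Phi^-1(target_auc)``, so its
    population AUROC is exactly ``target_auc``; ``scores_b = scores_a +
    N(0, perturbation_sd)`` shares the same cases (paired design).
    Returns ``(scores_a, scores_b, labels)``.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError(f"target_auc must lie in [0.5, 1), got {target_auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    mu = math.sqrt(2.0) * stats.norm.ppf(target_auc)
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    scores_a = rng.standard_normal(n_pos + n_neg)
    scores_a[:n_pos] += mu
    if perturbation_sd == 0.0:
        scores_b = scores_a.copy()
    else:
        scores_b = scores_a + rng.normal(0.0, perturbation_sd, size=scores_a.shape)
    return scores_a, scores_b, labels


def generate_prediction_set(
    n_pos: int,
    n_neg: int,
    target_auc: float,
    perturbation_sds: Mapping[str, float] | None = None,
    seed: int = 0,
) -> PredictionSet:
    """A full paired prediction set with original + dose conditions.

    Each alternative condition is the original score vector plus
    independent zero-mean noise of the requested SD — the fixture
    analogue of rescoring the same studies on noisier images.  Gender
    and view strata are drawn independently of the scores.
    """
    if perturbation_sds is None:
        perturbation_sds = {c: 0.1 for c in DOSE_CONDITIONS}
    rng = np.random.default_rng(seed)
    mu = math.sqrt(2.0) * stats.norm.ppf(target_auc)
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    base = rng.standard_normal(n_pos + n_neg)
    base[:n_pos] += mu
    scores = {"original": base}
    for cond, sd in perturbation_sds.items():
        scores[cond] = base + rng.normal(0.0, sd, size=base.shape)
    n = n_pos + n_neg
    return PredictionSet(
        study_ids=[f"s{i:07d}" for i in range(n)],
        labels=labels,
        scores=scores,
        strata={
            "gender": np.where(rng.random(n) < 0.5, "M", "F"),
            "view": np.where(rng.random(n) < 0.6, "PA", "AP"),
        },
    )
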