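"""Cohort curation rules for MIMIC-CXR-style pathology label tables.

Each study row carries one value per pathology: 1 (present), 0 (absent)
or -1 (uncertain).  Curation builds one balanced binary image set per
pathology:

* only certain labels are kept — rows with -1 for the pathology at hand
  are dropped;
* rows positively labelled under Support Devices are dropped (tubes and
  lines confound classification);
* the set is balanced 50/50 present/absent, capped at 10,000 studies;
* the set is split into train/validation/test at 0.7/0.2/0.1.

Seven pathologies are eligible for set construction (Atelectasis,
Cardiomegaly, Edema, Enlarged Cardiomediastinum, Fracture, Lung Lesion,
Pneumonia); Pneumothorax (drain confound), Support Devices, and the four
ambiguously worded labels (Lung Opacity, Consolidation, Pleural
Effusion, Pleural Other) are excluded.

The split sizes use round-half-to-even for train and validation, with
test taking the remainder; computed on exact rationals so that e.g. a
4670-study set yields 3269/934/467 and a 7185-study set 5030/1437/718
regardless of floating-point representation of the ratios.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INCLUDED_PATHOLOGIES",
    "EXCLUDED_PATHOLOGIES",
    "LabelRecord",
    "ImageSet",
    "filter_records",
    "build_balanced_set",
    "split_counts",
    "split_set",
    "derive_age",
    "records_to_dataframe",
    "dataframe_to_records",
    "read_label_csv",
    "write_label_csv",
    "write_split_manifest",
]

logger = logging.getLogger(__name__)

INCLUDED_PATHOLOGIES: tuple[str, ...] = (
    "Atelectasis",
    "Cardiomegaly",
    "Edema",
    "Enlarged Cardiomediastinum",
    "Fracture",
    "Lung Lesion",
    "Pneumonia",
)

EXCLUDED_PATHOLOGIES: tuple[str, ...] = (
    "Pneumothorax",
    "Support Devices",
    "Lung Opacity",
    "Consolidation",
    "Pleural Effusion",
    "Pleural Other",
)

DEFAULT_CAP = 10_000
DEFAULT_RATIOS = (0.7, 0.2, 0.1)
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class LabelRecord:
    """One study row of the label table."""

    study_id: str
    patient_id: str
    labels: dict[str, int] = field(default_factory=dict)
    support_devices: int | None = None  # 1 / 0 / -1, or None when absent
    gender: str = "F"
    view: str = "PA"
    anchor_age: float = 0.0
    anchor_year: int = 2100
    acquisition_date: _dt.date | None = None

    def __post_init__(self) -> None:
        bad = {p: v for p, v in self.labels.items() if v not in (1, 0, -1)}
        if bad:
            raise ValueError(f"labels must be 1/0/-1, got {bad}")


@dataclass
class ImageSet:
    """A balanced per-pathology set of studies, optionally split."""

    pathology: str
    members: list[tuple[str, str]]  # (study_id, "present"|"absent")
    split: dict[str, str] = field(default_factory=dict)  # study_id -> split name

    @property
    def size(self) -> int:
        return len(self.members)

    def split_sizes(self) -> dict[str, int]:
        sizes = {name: 0 for name in SPLIT_NAMES}
        for s in self.split.values():
            sizes[s] += 1
        return sizes


def _check_pathology(pathology: str) -> None:
    if pathology in EXCLUDED_PATHOLOGIES:
        raise ValueError(
            f"{pathology!r} is an excluded pathology (excluded set: "
            f"{', '.join(EXCLUDED_PATHOLOGIES)})"
        )
    if pathology not in INCLUDED_PATHOLOGIES:
        raise ValueError(
            f"unknown pathology {pathology!r}; eligible: {', '.join(INCLUDED_PATHOLOGIES)}"
        )


def filter_records(
    records: Sequence[LabelRecord], pathology: str
) -> tuple[list[LabelRecord], list[LabelRecord]]:
    """Apply the inclusion rules and partition by label.

    Drops rows whose label for ``pathology`` is uncertain (-1) and rows
    positively labelled under Support Devices (value 1 only; uncertain
    or missing Support Devices rows are kept).  Returns
    ``(present, absent)`` lists.
    """
    _check_pathology(pathology)
    present: list[LabelRecord] = []
    absent: list[LabelRecord] = []
    for rec in records:
        label = rec.labels.get(pathology)
        if label is None or label == -1:
            continue
        if rec.support_devices == 1:
            continue
        (present if label == 1 else absent).append(rec)
    return present, absent


def build_balanced_set(
    present: Sequence[LabelRecord | str],
    absent: Sequence[LabelRecord | str],
    cap: int = DEFAULT_CAP,
    rng: np.random.Generator | int | None = None,
    pathology: str = "",
) -> ImageSet:
    """Draw a 50/50 present/absent set of at most ``cap`` studies.

    ``min(cap // 2, n_present, n_absent)`` studies are sampled without
    replacement from each class, so scarce pathologies yield balance-
    limited sets smaller than the cap.
    """
    if cap % 2 != 0 or cap <= 0:
        raise ValueError(f"cap must be a positive even count, got {cap}")
    if len(present) == 0 or len(absent) == 0:
        raise ValueError(
            f"both classes must be non-empty (present={len(present)}, absent={len(absent)})"
        )
    rng = np.random.default_rng(rng)
    n = min(cap // 2, len(present), len(absent))

    def _ids(seq: Sequence[LabelRecord | str]) -> list[str]:
        return [r.study_id if isinstance(r, LabelRecord) else str(r) for r in seq]

    chosen_p = rng.choice(len(present), size=n, replace=False)
    chosen_a = rng.choice(len(absent), size=n, replace=False)
    p_ids, a_ids = _ids(present), _ids(absent)
    members = [(p_ids[i], "present") for i in sorted(chosen_p)]
    members += [(a_ids[i], "absent") for i in sorted(chosen_a)]
    return ImageSet(pathology=pathology, members=members)


def _round_half_even(n: int, ratio: Fraction) -> int:
    """round-half-to-even of n * ratio, on exact integers."""
    q, r = divmod(n * ratio.numerator, ratio.denominator)
    if 2 * r > ratio.denominator or (2 * r == ratio.denominator and q % 2 == 1):
        q += 1
    return q


def split_counts(
    n_total: int, ratios: Sequence[float] = DEFAULT_RATIOS
) -> tuple[int, int, int]:
    """Train/val/test sizes under the round-half-even + remainder rule."""
    if len(ratios) != 3:
        raise ValueError("ratios must have three entries (train, val, test)")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)!r}")
    fr = [Fraction(r).limit_denominator(10**6) for r in ratios]
    n_train = _round_half_even(n_total, fr[0])
    n_val = _round_half_even(n_total, fr[1])
    n_test = n_total - n_train - n_val
    if n_test < 0:
        raise ValueError(f"ratios {ratios} leave a negative test split for n={n_total}")
    return n_train, n_val, n_test


def split_set(
    image_set: ImageSet,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    rng: np.random.Generator | int | None = None,
    stratify: bool = True,
    patient_of: Mapping[str, str] | None = None,
) -> ImageSet:
    """Randomly assign members to train/val/test.

    With ``stratify=True`` (default) the present/absent classes are kept
    balanced within every split: global split sizes come from
    :func:`split_counts`, and odd-sized splits hand their extra study to
    alternating classes, so class balance within a split never deviates
    by more than one.  ``patient_of`` maps study_id -> patient_id; when
    given, all studies of one patient land in the same split (greedy
    fill, so split sizes may drift by a few studies from the exact rule).
    """
    rng = np.random.default_rng(rng)
    n = image_set.size
    n_train, n_val, n_test = split_counts(n, ratios)
    sizes = [n_train, n_val, n_test]

    if patient_of is not None:
        return _split_by_patient(image_set, sizes, rng, patient_of)

    assignment: dict[str, str] = {}
    if not stratify:
        order = rng.permutation(n)
        bounds = np.cumsum([0] + sizes)
        for name, lo, hi in zip(SPLIT_NAMES, bounds[:-1], bounds[1:]):
            for i in order[lo:hi]:
                assignment[image_set.members[i][0]] = name
    else:
        by_class: dict[str, list[str]] = {"present": [], "absent": []}
        for study_id, cls in image_set.members:
            by_class[cls].append(study_id)
        # distribute each split's size over the two classes: floor halves,
        # odd splits give their spare study to alternating classes
        class_counts = {"present": [], "absent": []}
        toggle = 0
        for s in sizes:
            extra_to = ("present", "absent")[toggle % 2] if s % 2 else None
            class_counts["present"].append(s // 2 + (extra_to == "present"))
            class_counts["absent"].append(s // 2 + (extra_to == "absent"))
            if s % 2:
                toggle += 1
        for cls in ("present", "absent"):
            ids = by_class[cls]
            if sum(class_counts[cls]) != len(ids):
                raise ValueError(
                    f"class {cls!r} has {len(ids)} members but the balanced split "
                    f"needs {sum(class_counts[cls])}; is the set balanced?"
                )
            order = rng.permutation(len(ids))
            bounds = np.cumsum([0] + class_counts[cls])
            for name, lo, hi in zip(SPLIT_NAMES, bounds[:-1], bounds[1:]):
                for i in order[lo:hi]:
                    assignment[ids[i]] = name

    return ImageSet(image_set.pathology, list(image_set.members), assignment)


def _split_by_patient(
    image_set: ImageSet,
    sizes: list[int],
    rng: np.random.Generator,
    patient_of: Mapping[str, str],
) -> ImageSet:
    patients: dict[str, list[str]] = {}
    for study_id, _ in image_set.members:
        patients.setdefault(patient_of.get(study_id, study_id), []).append(study_id)
    keys = list(patients)
    order = rng.permutation(len(keys))
    remaining = list(sizes)
    assignment: dict[str, str] = {}
    for i in order:
        studies = patients[keys[i]]
        # put the whole patient in the neediest split
        target = int(np.argmax(remaining))
        for s in studies:
            assignment[s] = SPLIT_NAMES[target]
        remaining[target] -= len(studies)
    return ImageSet(image_set.pathology, list(image_set.members), assignment)


def derive_age(
    anchor_age: float,
    anchor_year: int,
    acquisition_date: _dt.date | _dt.datetime | str,
) -> float:
    """Patient age at exposure from the de-identified anchor pair.

    ``age = anchor_age + (acquisition year - anchor year)``; a negative
    result is clamped to 0 with a warning (inconsistent metadata).
    """
    if anchor_age is None or anchor_year is None or acquisition_date is None:
        raise ValueError("anchor_age, anchor_year and acquisition_date are all required")
    if anchor_age < 0:
        raise ValueError(f"anchor_age must be >= 0, got {anchor_age}")
    if isinstance(acquisition_date, str):
        acquisition_date = _dt.date.fromisoformat(acquisition_date)
    year = acquisition_date.year
    age = anchor_age + (year - anchor_year)
    if age < 0:
        logger.warning(
            "derived age %g is negative (anchor %g@%d, acquired %s); clamping to 0",
            age, anchor_age, anchor_year, acquisition_date,
        )
        age = 0.0
    return float(age)


# ---------------------------------------------------------------------------
# CSV dialect (one column per pathology, values 1.0/0.0/-1.0/empty)
# ---------------------------------------------------------------------------

def records_to_dataframe(records: Iterable[LabelRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "study_id": rec.study_id,
            "patient_id": rec.patient_id,
            "gender": rec.gender,
            "view": rec.view,
            "anchor_age": rec.anchor_age,
            "anchor_year": rec.anchor_year,
            "acquisition_date": rec.acquisition_date.isoformat()
            if rec.acquisition_date
            else "",
        }
        for p, v in rec.labels.items():
            row[p] = float(v)
        if rec.support_devices is not None:
            row["Support Devices"] = float(rec.support_devices)
        rows.append(row)
    return pd.DataFrame(rows)


def dataframe_to_records(df: pd.DataFrame) -> list[LabelRecord]:
    meta_cols = {
        "study_id", "patient_id", "gender", "view",
        "anchor_age", "anchor_year", "acquisition_date",
    }
    pathology_cols = [c for c in df.columns if c not in meta_cols and c != "Support Devices"]
    records = []
    for _, row in df.iterrows():
        labels = {}
        for c in pathology_cols:
            v = row[c]
            if pd.notna(v) and str(v) != "":
                labels[c] = int(float(v))
        sd = None
        if "Support Devices" in df.columns and pd.notna(row["Support Devices"]) and str(row["Support Devices"]) != "":
            sd = int(float(row["Support Devices"]))
        acq = row.get("acquisition_date", "")
        acq_date = _dt.date.fromisoformat(str(acq)) if acq not in ("", None) and pd.notna(acq) else None
        records.append(
            LabelRecord(
                study_id=str(row["study_id"]),
                patient_id=str(row.get("patient_id", row["study_id"])),
                labels=labels,
                support_devices=sd,
                gender=str(row.get("gender", "F")),
                view=str(row.get("view", "PA")),
                anchor_age=float(row.get("anchor_age", 0.0)),
                anchor_year=int(row.get("anchor_year", 2100)),
                acquisition_date=acq_date,
            )
        )
    return records


def read_label_csv(path: str | Path) -> list[LabelRecord]:
    return dataframe_to_records(pd.read_csv(path))


def write_label_csv(records: Iterable[LabelRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def write_split_manifest(image_set: ImageSet, path: str | Path) -> None:
    """Write the (study_id, class, split) manifest as CSV."""
    rows = [
        {"study_id": sid, "class": cls, "split": image_set.split.get(sid, "")}
        for sid, cls in image_set.members
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
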