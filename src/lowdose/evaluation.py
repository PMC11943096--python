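"""Paired classifier-performance comparison for dose-reduction studies.

The central question — does simulating a lower radiation dose change a
classifier's discrimination? — is answered on *paired* data: the same
test studies are scored once on the original images and once per
simulated dose level.  Discrimination is summarised by the AUROC, which
equals the Mann-Whitney probability that a random positive outscores a
random negative (ties counted half).  Two correlated AUROCs are compared
with DeLong's nonparametric test, whose variance estimate is built from
per-case placement values (the fraction of opposite-class cases each
case outscores), so the covariance induced by scoring the same cases
twice is accounted for.

The full study design crosses seven pathologies with two input
resolutions (14 classifier configurations) and compares each baseline
against two simulated dose levels: 28 paired comparisons, evaluated
two-sided at alpha = 0.05 with no multiplicity correction by default
(an optional Holm adjustment is exposed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .curation import INCLUDED_PATHOLOGIES

__all__ = [
    "PredictionSet",
    "RocComparison",
    "auroc",
    "delong_test",
    "compare_conditions",
    "stratified_compare",
    "mann_whitney",
    "design_manifest",
    "RESOLUTIONS",
    "DOSE_CONDITIONS",
]

logger = logging.getLogger(__name__)

RESOLUTIONS: tuple[str, ...] = ("LR", "ULR")
DOSE_CONDITIONS: tuple[str, ...] = ("dose_050", "dose_025")


@dataclass
class PredictionSet:
    """Paired scores for one classifier on one test set.

    ``scores`` maps condition name (e.g. ``original``, ``dose_050``,
    ``dose_025``) to a score vector aligned with ``study_ids`` and
    ``labels``; every condition covers the same studies.
    """

    study_ids: list[str]
    labels: np.ndarray
    scores: dict[str, np.ndarray]
    strata: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n = len(self.study_ids)
        if self.labels.shape != (n,):
            raise ValueError("labels must align with study_ids")
        for cond, s in self.scores.items():
            s = np.asarray(s, dtype=np.float64)
            if s.shape != (n,):
                raise ValueError(f"scores[{cond!r}] must align with study_ids")
            self.scores[cond] = s
        for key, v in self.strata.items():
            v = np.asarray(v)
            if v.shape != (n,):
                raise ValueError(f"strata[{key!r}] must align with study_ids")
            self.strata[key] = v


@dataclass(frozen=True)
class RocComparison:
    """A paired AUROC comparison between two scoring conditions."""

    auroc_a: float
    auroc_b: float
    delta: float
    z: float
    p_value: float
    n_pos: int
    n_neg: int
    condition_a: str = "a"
    condition_b: str = "b"
    significant: bool | None = None
    stratum: str | None = None


def _split_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError(
            f"both classes required (n_pos={int(pos.sum())}, n_neg={int(neg.sum())})"
        )
    return pos, neg


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Midrank AUROC estimate.

    Equals the pair-counting definition
    ``(#(pos > neg) + 0.5 * #(pos == neg)) / (n_pos * n_neg)`` exactly,
    computed in O(n log n) via midranks.
    """
    s = np.asarray(scores, dtype=np.float64)
    pos, neg = _split_classes(np.asarray(labels))
    m, n = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def _placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """Per-case placement values (DeLong's structural components).

    For positive case i, V10_i = fraction of negatives it outscores
    (ties half); symmetrically V01_j for negatives.  The mean of either
    vector is the AUROC.
    """
    m, n = int(pos.sum()), int(neg.sum())
    all_ranks = stats.rankdata(scores)
    pos_ranks = stats.rankdata(scores[pos])
    neg_ranks = stats.rankdata(scores[neg])
    v10 = (all_ranks[pos] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[neg] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    condition_a: str = "a",
    condition_b: str = "b",
) -> RocComparison:
    """DeLong comparison of two correlated AUROCs on paired scores.

    Var(AUC_a - AUC_b) = Var(V10_a - V10_b)/m + Var(V01_a - V01_b)/n
    with sample variances (ddof=1) of the paired placement differences;
    this equals the S11 + S22 - 2*S12 form of the DeLong covariance
    matrix.  Two-sided p from the standard normal.  Being rank-based,
    the test is invariant under strictly monotone transforms of either
    score vector.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError(
            f"paired design requires equal lengths, got {a.shape}, {b.shape}, {y.shape}"
        )
    pos, neg = _split_classes(y)
    m, n = int(pos.sum()), int(neg.sum())
    v10a, v01a, auc_a = _placements(a, pos, neg)
    v10b, v01b, auc_b = _placements(b, pos, neg)
    delta = auc_a - auc_b
    var = 0.0
    if m > 1:
        var += float(np.var(v10a - v10b, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01a - v01b, ddof=1)) / n
    if var <= 0.0:
        if delta == 0.0:
            z, p = 0.0, 1.0
        else:
            logger.warning(
                "zero DeLong variance with non-zero AUROC difference %.4g", delta
            )
            z, p = float(np.sign(delta)) * np.inf, 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return RocComparison(
        auroc_a=auc_a, auroc_b=auc_b, delta=float(delta), z=float(z), p_value=p,
        n_pos=m, n_neg=n, condition_a=condition_a, condition_b=condition_b,
    )


def compare_conditions(
    preds: PredictionSet,
    baseline: str,
    alternatives: Sequence[str],
    alpha: float = 0.05,
    holm: bool = False,
) -> list[RocComparison]:
    """DeLong-compare a baseline condition against each alternative.

    Raw two-sided p-values are flagged at ``alpha`` with no multiplicity
    correction by default; ``holm=True`` applies a Holm step-down
    adjustment across the alternatives before flagging.
    """
    if baseline not in preds.scores:
        raise KeyError(f"baseline condition {baseline!r} not in predictions")
    missing = [c for c in alternatives if c not in preds.scores]
    if missing:
        raise KeyError(f"conditions missing from predictions: {missing}")
    comparisons = [
        delong_test(
            preds.scores[baseline], preds.scores[alt], preds.labels,
            condition_a=baseline, condition_b=alt,
        )
        for alt in alternatives
    ]
    pvals = np.array([c.p_value for c in comparisons])
    if holm and len(pvals):
        from statsmodels.stats.multitest import multipletests

        reject, adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
        flagged = list(reject)
    else:
        flagged = list(pvals < alpha)
    return [
        RocComparison(
            **{**c.__dict__, "significant": bool(f)}
        )
        for c, f in zip(comparisons, flagged)
    ]


def stratified_compare(
    preds: PredictionSet,
    by: str,
    baseline: str,
    alternatives: Sequence[str],
    alpha: float = 0.05,
) -> dict[str, list[RocComparison]]:
    """Run :func:`compare_conditions` within each stratum of ``by``.

    ``by`` must be a stratification key carried by the prediction set
    (typically ``gender`` or ``view``).  Strata containing a single
    class are skipped with a warning.
    """
    if by not in preds.strata:
        raise KeyError(
            f"unknown stratification key {by!r}; available: {sorted(preds.strata)}"
        )
    values = preds.strata[by]
    out: dict[str, list[RocComparison]] = {}
    for stratum in sorted(np.unique(values).tolist()):
        mask = values == stratum
        labels = preds.labels[mask]
        if len(np.unique(labels)) < 2:
            logger.warning(
                "stratum %s=%r has a single class (n=%d); skipped", by, stratum, mask.sum()
            )
            continue
        sub = PredictionSet(
            study_ids=[s for s, keep in zip(preds.study_ids, mask) if keep],
            labels=labels,
            scores={c: v[mask] for c, v in preds.scores.items()},
        )
        comps = compare_conditions(sub, baseline, alternatives, alpha=alpha)
        out[str(stratum)] = [
            RocComparison(**{**c.__dict__, "stratum": str(stratum)}) for c in comps
        ]
    return out


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact enumeration when both groups have <= 8 tie-free observations,
    otherwise the tie-corrected normal approximation.  Returns the U
    statistic of ``group_a`` and the two-sided p-value.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def design_manifest(
    pathologies: Sequence[str] | None = None,
    resolutions: Sequence[str] = RESOLUTIONS,
) -> list[dict[str, str]]:
    """Enumerate the classifier configurations of the study design.

    Seven pathologies x two input resolutions = 14 configurations; each
    is tested against ``len(DOSE_CONDITIONS)`` simulated dose levels,
    giving the 28 paired comparisons of the full design.
    """
    if pathologies is None:
        pathologies = INCLUDED_PATHOLOGIES
    return [
        {"pathology": p, "resolution": r} for p in pathologies for r in resolutions
    ]
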