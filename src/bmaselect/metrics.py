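"""Pooled and center-adjusted AUC for a biomarker combination score.

In a multicenter study, between-center differences in marker distributions
and outcome rates confound the pooled AUC: a score that merely encodes
"which center" can look discriminating.  The center-adjusted AUC removes
this by computing the Mann-Whitney AUC within each center and averaging
across centers, weighting by the number of cases per center (case-mix
standardization; pair-count weighting is available as an option).  Centers
without both a case and a control carry no within-center information and are
dropped with a warning — this arises routinely inside bootstrap resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["PerformanceEstimate", "pooled_auc", "center_adjusted_auc", "combination_score"]


@dataclass
class PerformanceEstimate:
    auc: float
    per_center: list[tuple[str, int, int, float]] = field(default_factory=list)
    dropped_centers: list[tuple[str, str]] = field(default_factory=list)
    weighting: str = "cases"


def pooled_auc(score: np.ndarray, label: np.ndarray) -> float:
    """Mann-Whitney AUC: P(case score > control score) with ties counted 1/2."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    n1 = int(np.sum(label == 1))
    n0 = int(np.sum(label == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one case and one control")
    ranks = rankdata(score)  # midranks handle ties as 1/2
    r1 = ranks[label == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def center_adjusted_auc(
    score: np.ndarray,
    label: np.ndarray,
    center: np.ndarray,
    weighting: str = "cases",
) -> PerformanceEstimate:
    """Weighted average of within-center Mann-Whitney AUCs.

    ``weighting="cases"`` weights each usable center by its case count;
    ``weighting="pairs"`` by its case*control pair count.  With a single
    center this reduces exactly to :func:`pooled_auc`.
    """
    if weighting not in ("cases", "pairs"):
        raise ValueError(f"unknown weighting {weighting!r}")
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    center = np.asarray(center)
    per_center: list[tuple[str, int, int, float]] = []
    dropped: list[tuple[str, str]] = []
    weights: list[float] = []
    aucs: list[float] = []
    for c in sorted(map(str, set(center.tolist()))):
        m = center.astype(str) == c
        n1 = int(np.sum(label[m] == 1))
        n0 = int(np.sum(label[m] == 0))
        if n1 == 0 or n0 == 0:
            reason = "no cases" if n1 == 0 else "no controls"
            dropped.append((c, reason))
            logger.debug("center %s dropped from adjusted AUC (%s)", c, reason)
            continue
        a = pooled_auc(score[m], label[m])
        per_center.append((c, n1, n0, a))
        weights.append(n1 if weighting == "cases" else n1 * n0)
        aucs.append(a)
    if not per_center:
        raise ValueError("no center has both cases and controls; adjusted AUC undefined")
    w = np.asarray(weights, dtype=float)
    auc = float(np.average(aucs, weights=w))
    return PerformanceEstimate(auc=auc, per_center=per_center, dropped_centers=dropped,
                               weighting=weighting)


def combination_score(coef_by_name: dict[str, float], matrix) -> np.ndarray:
    """Linear biomarker combination score over candidate columns only.

    Center-indicator and intercept terms are excluded: they shift scores by a
    within-center constant and therefore cannot change any within-center
    ranking (nor the adjusted AUC), and leaving them out keeps the score a
    pure biomarker combination.
    """
    score = np.zeros(matrix.n)
    candidate_names = set(matrix.candidate_names)
    for name, b in coef_by_name.items():
        if name == "(intercept)" or name.startswith("center_"):
            continue
        if name not in candidate_names:
            raise KeyError(f"coefficient {name!r} has no matching matrix column")
        score += b * matrix.X[:, matrix.columns.index(name)]
    return score
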