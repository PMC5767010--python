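"""Repeated stratified half-split comparison of selection procedures.

The data are split into training and test halves of (as near as possible)
equal size with equal numbers of primary-outcome cases.  Four procedures —
BMA maximum-posterior, BMA median-probability, forward selection
(p-to-enter 0.1) and univariate selection (per-marker p < 0.1, joint refit)
— are run on the training half; each selected combination is refit on the
training half and scored by center-adjusted AUC on the held-out half only.
Aggregates across splits: mean AUC, 2.5th/97.5th percentiles, and the
median/IQR of selected model size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .cohort import AnalysisMatrix
from .selectors import BMASelector, ForwardSelector, UnivariateSelector
from .validation import _selector_auc

logger = logging.getLogger(__name__)

__all__ = ["SplitConfig", "ComparisonReport", "stratified_half_split", "compare_selectors",
           "METHODS"]

METHODS = ("bma-max", "bma-median", "forward", "univariate")


@dataclass
class SplitConfig:
    n_splits: int = 1000
    p_enter: float = 0.1
    p_uni: float = 0.1
    seed: int = 0
    bma_search: str = "auto"

    def __post_init__(self):
        if not (0 < self.p_enter <= 1 and 0 < self.p_uni <= 1):
            raise ValueError("p-value thresholds must lie in (0, 1]")


@dataclass
class ComparisonReport:
    summary: pd.DataFrame  # one row per method
    per_split: pd.DataFrame  # long format: split, method, auc, size


def stratified_half_split(matrix: AnalysisMatrix, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of (train, test): cases and controls each split evenly.

    With an odd stratum count the training half receives the extra subject.
    Deterministic given the seed; halves are disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(matrix.y == 1)
    controls = np.flatnonzero(matrix.y == 0)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 cases and 2 controls to split")
    train_parts, test_parts = [], []
    for stratum in (cases, controls):
        perm = rng.permutation(stratum)
        k = (len(perm) + 1) // 2  # odd count: train gets the extra
        train_parts.append(perm[:k])
        test_parts.append(perm[k:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def _default_selectors(config: SplitConfig) -> dict[str, object]:
    return {
        "bma-max": BMASelector(rule="max", search=config.bma_search),
        "bma-median": BMASelector(rule="median", search=config.bma_search),
        "forward": ForwardSelector(p_enter=config.p_enter),
        "univariate": UnivariateSelector(p_uni=config.p_uni),
    }


def compare_selectors(matrix: AnalysisMatrix, config: SplitConfig | None = None) -> ComparisonReport:
    """Run the half-split experiment; the matrix must be complete-case."""
    if config is None:
        config = SplitConfig()
    selectors = _default_selectors(config)
    rng = np.random.default_rng(config.seed)
    rows = []
    for s in range(config.n_splits):
        split_seed = int(rng.integers(0, 2**31 - 1))
        tr, te = stratified_half_split(matrix, seed=split_seed)
        train, test = matrix.subset_rows(tr), matrix.subset_rows(te)
        for method, proto in selectors.items():
            sel = clone(proto).fit(train)
            auc = _selector_auc(sel, test)
            rows.append({"split": s, "method": method, "auc": auc, "size": len(sel.mask_)})
    per_split = pd.DataFrame(rows)

    summary_rows = []
    for method in METHODS:
        g = per_split[per_split.method == method]
        summary_rows.append({
            "method": method,
            "mean_auc": g.auc.mean(),
            "auc_p2.5": g.auc.quantile(0.025),
            "auc_p97.5": g.auc.quantile(0.975),
            "median_size": g["size"].median(),
            "size_q1": g["size"].quantile(0.25),
            "size_q3": g["size"].quantile(0.75),
        })
    return ComparisonReport(summary=pd.DataFrame(summary_rows), per_split=per_split)
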