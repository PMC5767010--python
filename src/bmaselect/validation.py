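"""Internal validation: apparent performance, bootstrap optimism, diagnostics.

The apparent (resubstitution) adjusted AUC of a data-selected combination is
optimistic for two reasons: the same data selected the model and the same
data evaluate it.  The correction repeats the *entire* selection procedure —
including the model-space search — inside every bootstrap resample.  For
replicate b the optimism is

    optimism_b = AUC(replicate-selected model on the resample)
               - AUC(the same fitted model on the original data)

and the corrected AUC is the apparent AUC minus the mean optimism.  A 95%
interval is the percentile interval of the bootstrap apparent AUCs, shifted
down by the mean optimism.  The secondary outcome (severe AKI) is scored in
the same loop: each replicate's primary-outcome selection is evaluated
against the secondary outcome on resample and original data.

Resampling is stratified by center by default so that every center is
represented and center-adjusted fitting is defined in every replicate; a
plain bootstrap is available via configuration.  Replicates that select the
empty combination contribute AUC 1/2 on both datasets (an empty biomarker
combination has no discrimination; dropping such replicates would bias the
optimism downward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .cohort import AnalysisMatrix
from .metrics import PerformanceEstimate, center_adjusted_auc
from .selectors import _BaseCombinationSelector

logger = logging.getLogger(__name__)

__all__ = ["ValidationConfig", "ValidationReport", "apparent_performance",
           "bootstrap_optimism", "optimism_shifted_ci", "cross_outcome_auc", "diagnostics"]


@dataclass
class ValidationConfig:
    n_boot: int = 1000
    seed: int = 0
    stratify_by_center: bool = True
    ci_level: float = 0.95

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class OutcomeValidation:
    """Validation summary for one outcome."""

    apparent_auc: float
    mean_optimism: float
    corrected_auc: float
    ci: tuple[float, float]
    boot_apparent: np.ndarray
    boot_original: np.ndarray


@dataclass
class ValidationReport:
    primary: OutcomeValidation
    cross_outcome: OutcomeValidation | None
    selected_mask: tuple[int, ...]
    selected_names: list[str]
    per_replicate: pd.DataFrame
    n_skipped: int
    config: ValidationConfig = field(default_factory=ValidationConfig)


def _safe_adjusted_auc(score, y, center) -> float | None:
    """Adjusted AUC, or None when no center is usable (degenerate replicate)."""
    try:
        return center_adjusted_auc(score, y, center).auc
    except ValueError:
        return None


def _selector_auc(selector, matrix: AnalysisMatrix, y=None) -> float:
    """Adjusted AUC of a fitted selector's score; empty selections score 1/2."""
    y = matrix.y if y is None else y
    if not selector.mask_:
        return 0.5
    score = selector.decision_function(matrix)
    auc = _safe_adjusted_auc(score, y, matrix.center)
    return 0.5 if auc is None else auc


def apparent_performance(
    matrix: AnalysisMatrix, selector: _BaseCombinationSelector
) -> tuple[tuple[int, ...], object, PerformanceEstimate]:
    """Run the selector on the full data and score it on the same data."""
    selector = clone(selector).fit(matrix)
    if not selector.mask_:
        logger.warning("selector returned the empty combination; apparent AUC set to 0.5")
        perf = PerformanceEstimate(auc=0.5, per_center=[], dropped_centers=[],
                                   weighting="cases")
    else:
        perf = center_adjusted_auc(selector.decision_function(matrix), matrix.y, matrix.center)
    return selector.mask_, selector.model_fit_, perf


def _resample_indices(rng, center: np.ndarray, stratify: bool) -> np.ndarray:
    n = len(center)
    if not stratify:
        return rng.integers(0, n, size=n)
    idx = []
    for c in np.unique(center):
        members = np.flatnonzero(center == c)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bootstrap_optimism(
    matrix: AnalysisMatrix,
    selector: _BaseCombinationSelector,
    config: ValidationConfig | None = None,
    secondary_y: np.ndarray | None = None,
) -> ValidationReport:
    """The full internal-validation loop (selection repeated per replicate)."""
    if config is None:
        config = ValidationConfig()
    rng = np.random.default_rng(config.seed)

    full_selector = clone(selector).fit(matrix)
    mask = full_selector.mask_
    apparent = _selector_auc(full_selector, matrix)
    apparent_sec = None
    if secondary_y is not None:
        apparent_sec = _selector_auc(full_selector, matrix, y=secondary_y)

    rows = []
    n_skipped = 0
    for b in range(config.n_boot):
        idx = _resample_indices(rng, matrix.center, config.stratify_by_center)
        boot = matrix.subset_rows(idx)
        if boot.y.min() == boot.y.max():
            n_skipped += 1
            logger.warning("replicate %d skipped: degenerate outcome", b)
            continue
        sel_b = clone(selector)
        try:
            sel_b.fit(boot)
        except RuntimeError as exc:
            n_skipped += 1
            logger.warning("replicate %d skipped: %s", b, exc)
            continue
        if sel_b.mask_:
            auc_boot = _safe_adjusted_auc(sel_b.decision_function(boot), boot.y, boot.center)
            auc_orig = _safe_adjusted_auc(sel_b.decision_function(matrix), matrix.y, matrix.center)
            if auc_boot is None or auc_orig is None:
                n_skipped += 1
                logger.warning("replicate %d skipped: no usable center for AUC", b)
                continue
        else:
            auc_boot = auc_orig = 0.5
        row = {
            "replicate": b,
            "boot_apparent_auc": auc_boot,
            "original_data_auc": auc_orig,
            "optimism": auc_boot - auc_orig,
            "selected_mask": sel_b.mask_,
            "selected_size": len(sel_b.mask_),
        }
        if hasattr(sel_b, "bma_result_"):
            from .bma import ModelSpec

            row["posterior_of_selected"] = sel_b.bma_result_.posterior_of(ModelSpec(sel_b.mask_))
        if secondary_y is not None:
            sec_boot = _selector_auc(sel_b, boot, y=secondary_y[idx])
            sec_orig = _selector_auc(sel_b, matrix, y=secondary_y)
            row["boot_secondary_auc"] = sec_boot
            row["original_secondary_auc"] = sec_orig
            row["optimism_secondary"] = sec_boot - sec_orig
        rows.append(row)

    if not rows:
        raise RuntimeError("all bootstrap replicates were skipped")
    per_rep = pd.DataFrame(rows)

    def summarize(app, boot_col, orig_col, opt_col) -> OutcomeValidation:
        optim = float(per_rep[opt_col].mean())
        boot_app = per_rep[boot_col].to_numpy(dtype=float)
        lo_q, hi_q = (1 - config.ci_level) / 2, 1 - (1 - config.ci_level) / 2
        lo = float(np.clip(np.quantile(boot_app, lo_q) - optim, 0, 1))
        hi = float(np.clip(np.quantile(boot_app, hi_q) - optim, 0, 1))
        return OutcomeValidation(
            apparent_auc=app,
            mean_optimism=optim,
            corrected_auc=app - optim,
            ci=(lo, hi),
            boot_apparent=boot_app,
            boot_original=per_rep[orig_col].to_numpy(dtype=float),
        )

    primary = summarize(apparent, "boot_apparent_auc", "original_data_auc", "optimism")
    cross = None
    if secondary_y is not None:
        cross = summarize(apparent_sec, "boot_secondary_auc", "original_secondary_auc",
                          "optimism_secondary")
    names = [matrix.candidate_names[i] for i in mask]
    return ValidationReport(
        primary=primary, cross_outcome=cross, selected_mask=mask, selected_names=names,
        per_replicate=per_rep, n_skipped=n_skipped, config=config,
    )


def optimism_shifted_ci(report: ValidationReport, min_replicates: int = 20) -> tuple[float, float]:
    """Percentile CI of bootstrap apparent AUCs, shifted by the mean optimism."""
    if len(report.per_replicate) < min_replicates:
        raise ValueError(
            f"only {len(report.per_replicate)} usable replicates; need >= {min_replicates}"
        )
    return report.primary.ci


def cross_outcome_auc(report: ValidationReport) -> OutcomeValidation:
    """Secondary-outcome validation computed inside the same bootstrap loop."""
    if report.cross_outcome is None:
        raise ValueError("report was produced without a secondary outcome")
    return report.cross_outcome


@dataclass
class DiagnosticsReport:
    boot_selected_posterior: pd.DataFrame
    boot_variable_probs: pd.DataFrame
    loo_variable_probs: pd.DataFrame
    boot_selected_auc: pd.DataFrame


def diagnostics(
    matrix: AnalysisMatrix,
    selector: _BaseCombinationSelector,
    config: ValidationConfig | None = None,
    loo_cap: int = 2000,
) -> DiagnosticsReport:
    """Bootstrap and leave-one-out stability diagnostics for a BMA selector.

    Tables: posterior of the full-data-selected combination per replicate
    (NaN when that combination fell outside the replicate's Occam window),
    per-replicate posterior variable probabilities, leave-one-out variable
    probabilities per observation, and the adjusted AUC of each replicate's
    selected combination on the original data.
    """
    from .bma import ModelSpec

    if config is None:
        config = ValidationConfig(n_boot=200)
    if matrix.n > loo_cap:
        raise ValueError(f"n={matrix.n} exceeds leave-one-out cap {loo_cap}")
    rng = np.random.default_rng(config.seed)
    names = matrix.candidate_names

    full = clone(selector).fit(matrix)
    full_spec = ModelSpec(full.mask_)

    post_rows, vp_rows, auc_rows = [], [], []
    for b in range(config.n_boot):
        idx = _resample_indices(rng, matrix.center, config.stratify_by_center)
        boot = matrix.subset_rows(idx)
        sel_b = clone(selector).fit(boot)
        res = sel_b.bma_result_
        post_rows.append({"replicate": b, "posterior_of_selected": res.posterior_of(full_spec)})
        vp_rows.append({"replicate": b, **res.variable_probs})
        auc_rows.append({
            "replicate": b,
            "selected_size": len(sel_b.mask_),
            "auc_original": _selector_auc(sel_b, matrix),
        })

    loo_rows = []
    keep = np.ones(matrix.n, dtype=bool)
    for i in range(matrix.n):
        keep[i] = False
        sel_i = clone(selector).fit(matrix.subset_rows(np.flatnonzero(keep)))
        keep[i] = True
        loo_rows.append({"observation": i, **sel_i.bma_result_.variable_probs})

    return DiagnosticsReport(
        boot_selected_posterior=pd.DataFrame(post_rows),
        boot_variable_probs=pd.DataFrame(vp_rows),
        loo_variable_probs=pd.DataFrame(loo_rows),
        boot_selected_auc=pd.DataFrame(auc_rows),
    )
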