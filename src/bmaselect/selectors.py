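"""Selection procedures as scikit-learn-style estimators.

Each selector is a deterministic function of the data: given a design matrix
containing candidate predictors and forced center-indicator columns, ``fit``
chooses a subset of the candidates, refits the chosen combination by
center-adjusted logistic regression, and exposes the combination score
(candidate terms only — no intercept, no center terms) through
``decision_function``.  The estimators compose with sklearn tooling
(``get_params``/``set_params``/``clone``), which is also how the bootstrap
and split harnesses re-run the entire selection per resample.

Selectors
---------
``BMASelector``
    Bayesian model averaging with BIC-approximated posteriors and Occam's
    window; ``rule="max"`` picks the maximum-posterior model, ``rule="median"``
    the median-probability model (variables with posterior probability > 1/2).
``ForwardSelector``
    Classic forward selection on Wald p-values with an entry threshold.
``UnivariateSelector``
    Keeps every candidate whose single-variable (center-adjusted) Wald
    p-value clears the threshold, then refits the kept set jointly.
``FixedSelector``
    A no-selection reference: refits a prespecified mask (used to show that
    optimism without selection is negligible).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .bma import BMAConfig, ModelSpec, fit_logistic, run_bma
from .cohort import AnalysisMatrix
from .logistic import ModelFit

__all__ = ["BMASelector", "ForwardSelector", "UnivariateSelector", "FixedSelector",
           "make_selector"]


def _as_matrix(X, y=None, forced_idx=None) -> AnalysisMatrix:
    if isinstance(X, AnalysisMatrix):
        return X
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    forced = np.zeros(k, dtype=bool)
    if forced_idx is not None:
        forced[np.asarray(forced_idx, dtype=int)] = True
    return AnalysisMatrix(
        X=X,
        y=np.asarray(y, dtype=float),
        columns=[f"x{i}" for i in range(k)],
        is_forced=forced,
        center=np.full(n, "pooled", dtype=object),
        outcome="y",
    )


class _BaseCombinationSelector(BaseEstimator):
    """Shared refit/score plumbing; subclasses implement ``_select``."""

    def fit(self, X, y=None):
        matrix = _as_matrix(X, y, getattr(self, "forced_idx", None))
        mask = self._select(matrix)
        self.mask_ = tuple(sorted(mask))
        self.n_features_in_ = matrix.X.shape[1]
        self._candidate_cols = matrix.candidate_idx.copy()
        self.selected_names_ = [matrix.candidate_names[i] for i in self.mask_]
        self.fit_ = fit_logistic(matrix, ModelSpec(self.mask_), compute_cov=True)
        coefs = self.fit_.coef_by_name()
        self.coef_ = np.array([coefs[n] for n in self.selected_names_])
        self.intercept_ = coefs["(intercept)"]
        return self

    def _select(self, matrix: AnalysisMatrix) -> tuple[int, ...]:  # pragma: no cover
        raise NotImplementedError

    def decision_function(self, X) -> np.ndarray:
        """Biomarker combination score (candidate columns only)."""
        if isinstance(X, AnalysisMatrix):
            X = X.X
        X = np.asarray(X, dtype=float)
        if not self.mask_:
            return np.zeros(X.shape[0])
        cols = self._candidate_cols[list(self.mask_)]
        return X[:, cols] @ self.coef_

    @property
    def model_fit_(self) -> ModelFit:
        return self.fit_


class BMASelector(_BaseCombinationSelector):
    def __init__(self, rule: str = "max", prior_pi: float = 0.5, occam_ratio: float = 20.0,
                 nbest: int = 50, search: str = "auto", forced_idx=None):
        self.rule = rule
        self.prior_pi = prior_pi
        self.occam_ratio = occam_ratio
        self.nbest = nbest
        self.search = search
        self.forced_idx = forced_idx

    def _select(self, matrix: AnalysisMatrix) -> tuple[int, ...]:
        if self.rule not in ("max", "median"):
            raise ValueError(f"unknown BMA selection rule {self.rule!r}")
        config = BMAConfig(prior_pi=self.prior_pi, occam_ratio=self.occam_ratio,
                           nbest=self.nbest, search=self.search)
        self.bma_result_ = run_bma(matrix, config)
        spec = self.bma_result_.max_model if self.rule == "max" else self.bma_result_.median_model
        return spec.included


def _wald_pvalues(fit: ModelFit, names: list[str]) -> dict[str, float]:
    if fit.cov is None:
        return {n: np.nan for n in names}
    se = np.sqrt(np.clip(np.diag(fit.cov), 0, None))
    out = {}
    for n in names:
        i = fit.columns.index(n)
        z = fit.coef[i] / se[i] if se[i] > 0 else 0.0
        out[n] = float(2 * norm.sf(abs(z)))
    return out


def _candidate_pvalue(matrix, base: list[int], j: int, criterion: str,
                      base_fit: ModelFit | None = None) -> float:
    """p-value for adding candidate ``j`` to ``base`` (Wald or likelihood ratio)."""
    fit = fit_logistic(matrix, ModelSpec(tuple(base + [j])),
                       compute_cov=criterion == "wald")
    if not fit.converged:
        return np.nan
    if criterion == "wald":
        name = matrix.candidate_names[j]
        return _wald_pvalues(fit, [name])[name]
    if base_fit is None:
        base_fit = fit_logistic(matrix, ModelSpec(tuple(base)))
    from scipy.stats import chi2

    lr = 2 * (fit.loglik - base_fit.loglik)
    return float(chi2.sf(max(lr, 0.0), 1))


class ForwardSelector(_BaseCombinationSelector):
    """Forward selection from the center-only model, no removal step.

    ``criterion`` chooses the per-step test: coefficient Wald z (default,
    one fit per candidate) or the likelihood-ratio chi-square.
    """

    def __init__(self, p_enter: float = 0.1, criterion: str = "wald", forced_idx=None):
        self.p_enter = p_enter
        self.criterion = criterion
        self.forced_idx = forced_idx

    def _select(self, matrix: AnalysisMatrix) -> tuple[int, ...]:
        if self.criterion not in ("wald", "lr"):
            raise ValueError(f"unknown test criterion {self.criterion!r}")
        p = len(matrix.candidate_idx)
        current: list[int] = []
        remaining = list(range(p))
        while remaining:
            base_fit = (fit_logistic(matrix, ModelSpec(tuple(current)))
                        if self.criterion == "lr" else None)
            best_p, best_j = None, None
            for j in remaining:
                pv = _candidate_pvalue(matrix, current, j, self.criterion, base_fit)
                if np.isnan(pv):
                    continue
                if best_p is None or pv < best_p:
                    best_p, best_j = pv, j
            if best_j is None or best_p >= self.p_enter:
                break
            current.append(best_j)
            remaining.remove(best_j)
        return tuple(current)


class UnivariateSelector(_BaseCombinationSelector):
    """Keep all candidates individually significant at ``p_uni``, refit jointly."""

    def __init__(self, p_uni: float = 0.1, criterion: str = "wald", forced_idx=None):
        self.p_uni = p_uni
        self.criterion = criterion
        self.forced_idx = forced_idx

    def _select(self, matrix: AnalysisMatrix) -> tuple[int, ...]:
        if self.criterion not in ("wald", "lr"):
            raise ValueError(f"unknown test criterion {self.criterion!r}")
        base_fit = (fit_logistic(matrix, ModelSpec(()))
                    if self.criterion == "lr" else None)
        keep = []
        for j in range(len(matrix.candidate_idx)):
            pv = _candidate_pvalue(matrix, [], j, self.criterion, base_fit)
            if not np.isnan(pv) and pv < self.p_uni:
                keep.append(j)
        return tuple(keep)


class FixedSelector(_BaseCombinationSelector):
    """Refit a prespecified candidate subset; performs no data-driven selection."""

    def __init__(self, mask: tuple[int, ...] = (), forced_idx=None):
        self.mask = mask
        self.forced_idx = forced_idx

    def _select(self, matrix: AnalysisMatrix) -> tuple[int, ...]:
        return tuple(self.mask)


def make_selector(name: str, **kwargs) -> _BaseCombinationSelector:
    """Selector registry used by the CLI: bma-max, bma-median, forward, univariate."""
    table = {
        "bma-max": lambda: BMASelector(rule="max", **kwargs),
        "bma-median": lambda: BMASelector(rule="median", **kwargs),
        "forward": lambda: ForwardSelector(**kwargs),
        "univariate": lambda: UnivariateSelector(**kwargs),
    }
    if name not in table:
        raise ValueError(f"unknown selector {name!r}; choose from {sorted(table)}")
    return table[name]()
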