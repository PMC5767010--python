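"""Maximum-likelihood logistic regression via iteratively reweighted least squares.

This is the numerical core under the model-averaging machinery: every
candidate model (a subset of biomarker columns plus the forced center
indicators and an intercept) is fit by Newton/IRLS.  A batched fitter
evaluates many candidate models of a model-space enumeration at once using
stacked BLAS calls, which is what makes exhaustive enumeration and the
bootstrap loops tractable on one CPU.

Convergence is declared when the largest coefficient change drops below
1e-8 (at most 25 iterations).  One special case is tolerated: in bootstrap
resamples a small center can end up with zero events, and its forced
indicator coefficient then drifts to minus infinity while the likelihood and
every candidate coefficient are fully converged.  Such fits are accepted
(warning ``forced_cell_separation``) because the drifting parameter is the
same forced block in every candidate model and its likelihood contribution
has plateaued.  Separation in a *candidate* coefficient is flagged and the
fit reported as non-converged, so callers can drop it from the posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

MAX_ITER = 25
TOL = 1e-8
#: relative deviance-change threshold for the forced-cell plateau rule
DEV_TOL = 1e-8
#: |log-odds coefficient| beyond which a still-moving candidate is separated
COEF_RUNAWAY = 30.0
_WMIN = 1e-10

__all__ = ["ModelFit", "fit_logistic_arrays", "batch_fit_logistic", "log_likelihood"]


@dataclass
class ModelFit:
    """A fitted logistic model: coefficients, likelihood, BIC, convergence."""

    coef: np.ndarray  # intercept, forced covariates, included candidates (in column order)
    columns: list[str]
    loglik: float
    df: int
    bic: float
    converged: bool
    warning: str | None = None
    cov: np.ndarray | None = None  # inverse observed information (for Wald tests)

    def coef_by_name(self) -> dict[str, float]:
        return dict(zip(self.columns, self.coef.tolist()))


def log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood at linear predictor ``eta`` (numerically safe)."""
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _infer_forced(columns: list[str]) -> np.ndarray:
    return np.array([c == "(intercept)" or c.startswith("center_") for c in columns])


def fit_logistic_arrays(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
    add_intercept: bool = True,
    compute_cov: bool = False,
    forced: np.ndarray | None = None,
) -> ModelFit:
    """IRLS fit of a single logistic model.

    ``X`` holds the model's columns (forced + included candidates) without an
    intercept; one is prepended unless ``add_intercept`` is false.  ``forced``
    marks the columns (after intercept insertion) covered by the plateau rule
    above; by default it is inferred from the column names.
    """
    n = X.shape[0]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        columns = ["(intercept)"] + list(columns or [f"x{i}" for i in range(X.shape[1] - 1)])
    elif columns is None:
        columns = [f"x{i}" for i in range(X.shape[1])]
    if forced is None:
        forced = _infer_forced(columns)
    k = X.shape[1]
    beta = np.zeros(k)
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    if add_intercept:
        beta[0] = np.log(ybar / (1 - ybar))

    converged = False
    warning = None
    XtWX = np.empty((k, k))
    dev_prev = np.inf
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), _WMIN, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        Xtwz = Xw.T @ z
        try:
            beta_new = np.linalg.solve(XtWX, Xtwz)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(XtWX, Xtwz, rcond=None)
            warning = "singular_information"
        delta = np.abs(beta_new - beta)
        beta = beta_new
        if not np.all(np.isfinite(beta)):
            warning = "separation"
            break
        cand_moving = delta > TOL
        cand_moving[forced] = False
        if np.any(np.abs(beta[~forced]) > COEF_RUNAWAY):
            warning = "separation"
            break
        dev = -2.0 * log_likelihood(X @ beta, y)
        if delta.max() < TOL:
            converged = warning is None
            break
        if (not cand_moving.any()) and abs(dev_prev - dev) < DEV_TOL * (abs(dev) + 1.0):
            # only forced coefficients still drifting, likelihood plateaued
            converged = warning is None
            warning = warning or "forced_cell_separation"
            break
        dev_prev = dev
    else:
        warning = warning or "max_iter"
    if not converged and warning is None:
        warning = "separation"

    eta = X @ beta if np.all(np.isfinite(beta)) else np.zeros(n)
    ll = log_likelihood(eta, y) if np.all(np.isfinite(beta)) else -np.inf
    bic = -2.0 * ll + k * np.log(n)
    cov = None
    if compute_cov and converged:
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            cov = None
    return ModelFit(
        coef=beta, columns=list(columns), loglik=ll, df=k, bic=bic,
        converged=converged, warning=warning, cov=cov,
    )


def batch_fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    col_idx: np.ndarray,
    n_forced: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit many logistic models sharing data but differing in columns.

    ``col_idx`` is an ``(m, k)`` integer array: model ``i`` uses columns
    ``col_idx[i]`` of ``X`` plus an intercept (all models in a batch share a
    size ``k``; callers group an enumeration by model size).  The first
    ``n_forced`` entries of every row must be the forced columns.

    Returns ``(coefs, loglik, bic, converged)`` with ``coefs`` of shape
    ``(m, k+1)`` (intercept first, then columns in ``col_idx`` order).
    IRLS with per-model convergence tracking; models drop out of the active
    batch as they converge.
    """
    m, k = col_idx.shape
    n = X.shape[0]
    Xg = np.empty((m, n, k + 1))
    Xg[:, :, 0] = 1.0
    if k:
        Xg[:, :, 1:] = np.transpose(X[:, col_idx], (1, 0, 2))
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    beta = np.zeros((m, k + 1))
    beta[:, 0] = np.log(ybar / (1 - ybar))
    cand_cols = np.arange(k + 1) > n_forced  # candidate positions (after intercept+forced)

    converged = np.zeros(m, dtype=bool)
    failed = np.zeros(m, dtype=bool)
    dev_prev = np.full(m, np.inf)
    active = np.arange(m)
    yv = y[None, :, None]

    for _ in range(MAX_ITER):
        Xa = Xg[active]
        ba = beta[active]
        eta = np.matmul(Xa, ba[:, :, None])  # (a, n, 1)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), _WMIN, None)
        z = eta + (yv - mu) / w
        Xw = Xa * w
        A = np.matmul(np.transpose(Xa, (0, 2, 1)), Xw)
        b = np.matmul(np.transpose(Xw, (0, 2, 1)), z)[:, :, 0]
        try:
            beta_new = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta_new = np.empty_like(ba)
            for j in range(len(active)):
                try:
                    beta_new[j] = np.linalg.solve(A[j], b[j])
                except np.linalg.LinAlgError:
                    beta_new[j] = np.linalg.lstsq(A[j], b[j], rcond=None)[0]
                    failed[active[j]] = True
        delta = np.abs(beta_new - ba)
        beta[active] = beta_new

        nonfinite = ~np.all(np.isfinite(beta_new), axis=1)
        if cand_cols.any():
            runaway = np.any(np.abs(beta_new[:, cand_cols]) > COEF_RUNAWAY, axis=1)
        else:
            runaway = np.zeros(len(active), dtype=bool)
        bad = nonfinite | runaway
        failed[active[bad]] = True

        coef_done = np.max(delta, axis=1) < TOL
        if cand_cols.any():
            cand_delta = np.max(delta[:, cand_cols], axis=1)
        else:
            cand_delta = np.zeros(len(active))
        # deviance-plateau check only for the (few) models whose candidate
        # coefficients are stationary but whose forced block is still drifting
        plateau = np.zeros(len(active), dtype=bool)
        sub = np.flatnonzero((cand_delta < TOL) & ~coef_done & ~bad)
        if len(sub):
            eta_sub = np.matmul(Xa[sub], beta_new[sub][:, :, None])[:, :, 0]
            with np.errstate(invalid="ignore", over="ignore"):
                dev = -2.0 * np.sum(y[None, :] * eta_sub - np.logaddexp(0.0, eta_sub), axis=1)
            plateau[sub] = np.abs(dev_prev[active[sub]] - dev) < DEV_TOL * (np.abs(dev) + 1.0)
            dev_prev[active[sub]] = dev

        done = coef_done | plateau | bad
        converged[active[done & ~bad]] = True
        active = active[~done]
        if len(active) == 0:
            break
    converged &= ~failed

    eta_all = np.matmul(Xg, beta[:, :, None])[:, :, 0]
    with np.errstate(invalid="ignore", over="ignore"):
        ll = np.sum(y[None, :] * eta_all - np.logaddexp(0.0, eta_all), axis=1)
    ll[~np.all(np.isfinite(beta), axis=1)] = -np.inf
    bic = -2.0 * ll + (k + 1) * np.log(n)
    return beta, ll, bic, converged
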