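"""Bayesian model averaging for center-adjusted logistic regression.

Every candidate model is a subset of the p candidate predictors; the center
indicators (and the intercept) are forced into every model and carry prior
inclusion probability 1.  Each candidate predictor has independent prior
inclusion probability ``prior_pi`` (default 1/2, so each of the 2^p models is
a priori equally likely; with p=23 that is a prior model probability of
(1/2)^23 ≈ 1.19e-7 over 8,388,608 models).

The integrated likelihood of each model is approximated through its BIC, the
standard approximation in BMA for generalized linear models: the
unnormalized posterior of model k is

    exp(-(BIC_k - BIC_min)/2) * pi^|k| * (1-pi)^(p-|k|).

Models whose posterior odds against the best model exceed ``occam_ratio``
(Occam's window, default 20) are discarded and the survivors renormalized.
The posterior variable probability of a predictor is the summed posterior of
retained models containing it; the two selection rules are the
maximum-posterior model and the median-probability model (all predictors with
variable probability strictly above 1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cohort import AnalysisMatrix
from .logistic import ModelFit, batch_fit_logistic, fit_logistic_arrays
from .subsets import best_subsets_wls

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "BMAConfig",
    "BMAResult",
    "fit_logistic",
    "candidate_models",
    "posterior_probabilities",
    "select_max_posterior",
    "select_median_probability",
    "run_bma",
]

EXHAUSTIVE_P_MAX = 16  # 2^16 exact fits is still desk scale


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: the included candidate predictors (positions in the
    matrix's candidate order).  Forced center columns are implicit."""

    included: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "included", tuple(sorted(self.included)))

    @property
    def size(self) -> int:
        return len(self.included)

    def bitmask(self) -> int:
        m = 0
        for i in self.included:
            m |= 1 << i
        return m


@dataclass
class BMAConfig:
    prior_pi: float = 0.5
    occam_ratio: float = 20.0
    nbest: int = 50
    search: str = "auto"  # "exhaustive" | "leaps" | "auto"
    #: slack (log posterior-odds units) added to the Occam window when the
    #: screening stage discards models using linearized-problem BICs; only
    #: models surviving the widened window are refit exactly.
    screen_margin: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prior_pi < 1:
            raise ValueError("prior_pi must lie in (0, 1)")
        if self.occam_ratio <= 1:
            raise ValueError("occam_ratio must exceed 1")
        if self.nbest < 1:
            raise ValueError("nbest must be >= 1")
        if self.search not in ("exhaustive", "leaps", "auto"):
            raise ValueError(f"unknown search mode {self.search!r}")


@dataclass
class BMAResult:
    models: list[tuple[ModelSpec, ModelFit, float]]  # retained, with posterior probs
    variable_probs: dict[str, float]
    max_model: ModelSpec
    median_model: ModelSpec
    n_candidates_evaluated: int
    candidate_names: list[str] = field(default_factory=list)

    def posterior_of(self, spec: ModelSpec) -> float | None:
        for s, _, post in self.models:
            if s.included == spec.included:
                return post
        return None


# ---------------------------------------------------------------------------


def fit_logistic(matrix: AnalysisMatrix, spec: ModelSpec, compute_cov: bool = False) -> ModelFit:
    """Exact IRLS fit of one candidate model (forced columns always included)."""
    cand = matrix.candidate_idx
    cols = np.concatenate([matrix.forced_idx, cand[list(spec.included)]]).astype(int)
    names = [matrix.columns[i] for i in cols]
    forced = np.zeros(len(cols) + 1, dtype=bool)
    forced[: len(matrix.forced_idx) + 1] = True  # intercept + center block
    return fit_logistic_arrays(matrix.X[:, cols], matrix.y, columns=names,
                               compute_cov=compute_cov, forced=forced)


def candidate_models(matrix: AnalysisMatrix, config: BMAConfig) -> list[ModelSpec]:
    """Enumerate (p<=16 or search='exhaustive') or screen via branch-and-bound.

    The leaps path fits the full logistic model by IRLS, forms the weighted
    linearized regression at the solution, and runs exact branch-and-bound
    best-subsets keeping ``nbest`` models per size; exact logistic BICs are
    recomputed later for every returned spec.
    """
    p = len(matrix.candidate_idx)
    search = config.search
    if search == "auto":
        search = "exhaustive" if p <= EXHAUSTIVE_P_MAX else "leaps"
    if search == "exhaustive":
        return [ModelSpec(tuple(i for i in range(p) if m >> i & 1)) for m in range(2**p)]

    # leaps: linearize at the full-model fit
    full = ModelSpec(tuple(range(p)))
    fit = fit_logistic(matrix, full)
    if not fit.converged:
        if p <= EXHAUSTIVE_P_MAX:
            logger.warning("full-model IRLS failed; falling back to exhaustive search")
            return candidate_models(matrix, BMAConfig(**{**config.__dict__, "search": "exhaustive"}))
        raise RuntimeError("full-model IRLS did not converge; leaps screening unavailable")
    cols = np.concatenate([matrix.forced_idx, matrix.candidate_idx]).astype(int)
    Xfit = np.column_stack([np.ones(matrix.n), matrix.X[:, cols]])
    eta = Xfit @ fit.coef
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    z = eta + (matrix.y - mu) / w
    subsets = best_subsets_wls(
        matrix.X, z, w,
        cand_idx=matrix.candidate_idx,
        forced_idx=matrix.forced_idx,
        nbest=config.nbest,
    )
    # screen on approximate posteriors: on the linearized problem the deviance
    # change of subset S vs the full model is RSS_S - RSS_full, so up to a
    # constant  logpost(S) ~= -(RSS_S + |S| log n)/2 + |S| log pi
    #                         + (p - |S|) log(1 - pi).
    # Models outside the Occam window widened by `screen_margin` cannot
    # plausibly survive the exact window and are not refit.
    logn = np.log(matrix.n)
    pi = config.prior_pi
    items = list(subsets.items())
    lp = np.array([
        -0.5 * (rss + len(s) * logn) + len(s) * np.log(pi) + (p - len(s)) * np.log1p(-pi)
        for s, rss in items
    ])
    keep = lp >= lp.max() - (np.log(config.occam_ratio) + config.screen_margin)
    kept = sorted((s for (s, _), k in zip(items, keep) if k), key=lambda t: (len(t), t))
    return [ModelSpec(s) for s in kept]


def posterior_probabilities(
    fits: list[tuple[ModelSpec, ModelFit]],
    config: BMAConfig,
    n: int,
    p: int,
    candidate_names: list[str] | None = None,
    n_candidates_evaluated: int | None = None,
) -> BMAResult:
    """BIC-approximated posteriors with Occam's window and both selection rules."""
    ok = [(s, f) for s, f in fits if f.converged]
    dropped = len(fits) - len(ok)
    if dropped:
        logger.warning("dropping %d non-converged candidate fits from the posterior", dropped)
    if not ok:
        raise RuntimeError("no converged candidate fits; posterior undefined")

    pi = config.prior_pi
    bics = np.array([f.bic for _, f in ok])
    sizes = np.array([s.size for s, _ in ok])
    logpost = -0.5 * (bics - bics.min()) + sizes * np.log(pi) + (p - sizes) * np.log1p(-pi)
    logpost -= logpost.max()
    keep = logpost >= -np.log(config.occam_ratio)
    retained = [(s, f) for (s, f), k in zip(ok, keep) if k]
    lp = logpost[keep]
    probs = np.exp(lp)
    probs /= probs.sum()

    names = candidate_names or [f"x{i}" for i in range(p)]
    var_probs = {name: 0.0 for name in names}
    for (spec, _), pr in zip(retained, probs):
        for i in spec.included:
            var_probs[names[i]] += float(pr)

    order = sorted(
        range(len(retained)),
        key=lambda i: (-probs[i], retained[i][0].size, retained[i][0].bitmask()),
    )
    max_model = retained[order[0]][0]
    median_model = ModelSpec(tuple(i for i, name in enumerate(names) if var_probs[name] > 0.5))

    models = [(retained[i][0], retained[i][1], float(probs[i])) for i in order]
    return BMAResult(
        models=models,
        variable_probs=var_probs,
        max_model=max_model,
        median_model=median_model,
        n_candidates_evaluated=n_candidates_evaluated if n_candidates_evaluated is not None else len(fits),
        candidate_names=names,
    )


def select_max_posterior(result: BMAResult) -> ModelSpec:
    return result.max_model


def select_median_probability(result: BMAResult) -> ModelSpec:
    return result.median_model


def _batched_fits(matrix: AnalysisMatrix, specs: list[ModelSpec]) -> list[tuple[ModelSpec, ModelFit]]:
    """Exact IRLS fits for many specs, batched by model size."""
    cand = matrix.candidate_idx
    forced = matrix.forced_idx
    by_size: dict[int, list[ModelSpec]] = {}
    for s in specs:
        by_size.setdefault(s.size, []).append(s)
    out: list[tuple[ModelSpec, ModelFit]] = []
    for size, group in sorted(by_size.items()):
        col_idx = np.array(
            [np.concatenate([forced, cand[list(s.included)]]).astype(int) for s in group]
        )
        coefs, ll, bic, conv = batch_fit_logistic(
            matrix.X, matrix.y, col_idx, n_forced=len(forced)
        )
        k = col_idx.shape[1] + 1
        for j, s in enumerate(group):
            names = ["(intercept)"] + [matrix.columns[i] for i in col_idx[j]]
            out.append(
                (
                    s,
                    ModelFit(
                        coef=coefs[j], columns=names, loglik=float(ll[j]), df=k,
                        bic=float(bic[j]), converged=bool(conv[j]),
                        warning=None if conv[j] else "separation_or_nonconvergence",
                    ),
                )
            )
    return out


def run_bma(matrix: AnalysisMatrix, config: BMAConfig | None = None) -> BMAResult:
    """Full pipeline: model search, exact fits, posterior probabilities."""
    if config is None:
        config = BMAConfig()
    specs = candidate_models(matrix, config)
    fits = _batched_fits(matrix, specs)
    return posterior_probabilities(
        fits, config, n=matrix.n, p=len(matrix.candidate_idx),
        candidate_names=matrix.candidate_names,
        n_candidates_evaluated=len(specs),
    )
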