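"""Association of a fixed biomarker combination with post-surgery mortality.

The combination score is taken as fixed (its coefficients estimated for the
AKI outcome are not re-estimated), standardized to unit sample SD, and
entered into a logistic regression for death with center-specific intercepts.
The association is reported as an odds ratio per SD of the score with a Wald
95% confidence interval.  Complete cases on the combination's own biomarkers
and the death outcome are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .logistic import fit_logistic_arrays

__all__ = ["AssociationResult", "mortality_association"]


@dataclass
class AssociationResult:
    odds_ratio_per_sd: float
    ci: tuple[float, float]
    n_used: int
    outcome: str
    score_sd: float


def mortality_association(
    score: np.ndarray,
    death: np.ndarray,
    center: np.ndarray,
    outcome: str = "death",
    ci_level: float = 0.95,
) -> AssociationResult:
    """Center-adjusted odds ratio per SD of a fixed combination score."""
    score = np.asarray(score, dtype=float)
    death = np.asarray(death, dtype=float)
    center = np.asarray(center).astype(str)
    ok = ~np.isnan(score) & ~np.isnan(death)
    score, death, center = score[ok], death[ok], center[ok]
    if len(np.unique(death)) < 2:
        raise ValueError("death outcome is degenerate (all 0 or all 1)")
    sd = float(score.std(ddof=1))
    if sd == 0:
        raise ValueError("combination score has zero variance")
    z = (score - score.mean()) / sd

    levels = sorted(set(center.tolist()))
    indicators = [(center == lev).astype(float) for lev in levels[1:]]
    X = np.column_stack([*indicators, z]) if indicators else z[:, None]
    names = [f"center_{lev}" for lev in levels[1:]] + ["score_sd"]
    fit = fit_logistic_arrays(X, death, columns=names, compute_cov=True)
    if not fit.converged or fit.cov is None:
        raise RuntimeError(f"mortality logistic fit failed ({fit.warning})")
    i = fit.columns.index("score_sd")
    beta = fit.coef[i]
    se = float(np.sqrt(fit.cov[i, i]))
    zq = norm.ppf(1 - (1 - ci_level) / 2)
    return AssociationResult(
        odds_ratio_per_sd=float(np.exp(beta)),
        ci=(float(np.exp(beta - zq * se)), float(np.exp(beta + zq * se))),
        n_used=int(len(death)),
        outcome=outcome,
        score_sd=sd,
    )
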