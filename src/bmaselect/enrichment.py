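"""Prognostic-enrichment calculations for trial design.

Enrolling only subjects whose biomarker combination score exceeds a
percentile threshold raises the event rate among enrollees, shrinking the
trial, at the cost of screening 1/(1-q) candidates per enrollee.  For each
threshold the table reports the number to screen, the event rate among
screen-positives, and the total two-arm sample size for a treatment that
reduces event risk by a fixed relative amount, at the given power and
two-sided alpha (normal approximation for two independent proportions with
unpooled variances; per-arm size rounded up, equal arms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["TrialDesign", "EnrichmentRow", "number_to_screen", "screen_positive_event_rate",
           "two_arm_sample_size", "enrichment_table", "simulated_power"]


@dataclass
class TrialDesign:
    power: float = 0.90
    alpha: float = 0.05  # two-sided
    relative_risk_reduction: float = 0.30

    def __post_init__(self):
        for name in ("power", "alpha", "relative_risk_reduction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class EnrichmentRow:
    threshold_percentile: float
    number_to_screen: float
    event_rate_screen_pos: float
    total_sample_size: int
    combination: str = ""


def number_to_screen(q: float) -> float:
    """Subjects screened per eligible subject at percentile threshold q: 1/(1-q),
    reported to one decimal."""
    if not 0 <= q < 1:
        raise ValueError("threshold percentile must lie in [0, 1)")
    return round(1.0 / (1.0 - q), 1)


def screen_positive_event_rate(score: np.ndarray, outcome: np.ndarray, q: float) -> float:
    """Event proportion among subjects strictly above the empirical q-quantile."""
    if not 0 <= q < 1:
        raise ValueError("threshold percentile must lie in [0, 1)")
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if q == 0:
        return float(outcome.mean())
    thr = np.quantile(score, q)
    pos = score > thr
    if not pos.any():
        raise ValueError(f"no screen positives above the {q:.0%} threshold (constant score?)")
    return float(outcome[pos].mean())


def two_arm_sample_size(p_control: float, design: TrialDesign | None = None) -> int:
    """Total N (two equal arms) to detect the treatment effect on an event rate.

    Normal approximation for the difference of two proportions with unpooled
    variances:  n/arm = (z_{1-a/2} + z_{power})^2 (p0 q0 + p1 q1) / (p0-p1)^2.
    """
    if design is None:
        design = TrialDesign()
    if not 0 < p_control < 1:
        raise ValueError("control event rate must lie in (0, 1)")
    rrr = design.relative_risk_reduction
    p_treat = p_control * (1 - rrr)
    if p_treat <= 0 or p_treat >= p_control:
        raise ValueError("treatment effect must strictly reduce the event rate")
    za = norm.ppf(1 - design.alpha / 2)
    zb = norm.ppf(design.power)
    num = (za + zb) ** 2 * (p_control * (1 - p_control) + p_treat * (1 - p_treat))
    n_arm = math.ceil(num / (p_control - p_treat) ** 2)
    return 2 * n_arm


def simulated_power(p_control: float, total_n: int, design: TrialDesign | None = None,
                    n_trials: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo power of the two-proportion z-test at a given total N.

    Independent oracle for :func:`two_arm_sample_size`: simulates ``n_trials``
    trials with ``total_n/2`` per arm and counts rejections of the unpooled
    z-test at the design's two-sided alpha.
    """
    if design is None:
        design = TrialDesign()
    rng = np.random.default_rng(seed)
    n_arm = total_n // 2
    p1 = p_control * (1 - design.relative_risk_reduction)
    x0 = rng.binomial(n_arm, p_control, size=n_trials)
    x1 = rng.binomial(n_arm, p1, size=n_trials)
    ph0 = x0 / n_arm
    ph1 = x1 / n_arm
    se = np.sqrt(ph0 * (1 - ph0) / n_arm + ph1 * (1 - ph1) / n_arm)
    se = np.where(se == 0, np.nan, se)
    z = (ph0 - ph1) / se
    za = norm.ppf(1 - design.alpha / 2)
    reject = np.abs(z) > za
    return float(np.nanmean(np.where(np.isnan(z), ph0 != ph1, reject)))


def enrichment_table(
    scores: dict[str, np.ndarray],
    outcome: np.ndarray,
    percentiles: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75),
    design: TrialDesign | None = None,
) -> list[EnrichmentRow]:
    """One row per (threshold, combination); the q=0 row uses the overall rate."""
    if design is None:
        design = TrialDesign()
    rows: list[EnrichmentRow] = []
    for q in percentiles:
        if q == 0:
            rate = screen_positive_event_rate(next(iter(scores.values())), outcome, 0.0)
            rows.append(EnrichmentRow(
                threshold_percentile=0.0,
                number_to_screen=number_to_screen(0.0),
                event_rate_screen_pos=rate,
                total_sample_size=two_arm_sample_size(rate, design),
                combination="(none)",
            ))
            continue
        for name, score in scores.items():
            rate = screen_positive_event_rate(score, outcome, q)
            rows.append(EnrichmentRow(
                threshold_percentile=q,
                number_to_screen=number_to_screen(q),
                event_rate_screen_pos=rate,
                total_sample_size=two_arm_sample_size(rate, design),
                combination=name,
            ))
    return rows
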