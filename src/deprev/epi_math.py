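"""Pure epidemiological arithmetic shared by the cohort model and the PSA.

Rate/probability conversion follows the standard actuarial pair used in
decision modelling: a probability ``p`` over a horizon of
``t`` months corresponds to a constant hazard ``r = -ln(1 - p) / t`` per
month, and conversely ``p = 1 - exp(-r t)``.  Treatment effects expressed
as odds ratios can be applied to a baseline risk either on the odds scale
(the textbook conversion) or directly as a risk multiplier; both are
implemented here and the cohort model selects between them.
"""

from __future__ import annotations

import math
from typing import NamedTuple

__all__ = [
    "prob_to_rate",
    "rate_to_prob",
    "rescale_probability",
    "apply_odds_ratio",
    "apply_effect",
    "TwoByTwo",
    "OddsRatioResult",
    "odds_ratio_from_counts",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "lognormal_from_or_ci",
    "lognormal_from_or_se",
]


def prob_to_rate(p: float, horizon_months: float) -> float:
    """Convert a probability over ``horizon_months`` to a hazard per month.

    ``r = -ln(1 - p) / horizon``.  A probability of exactly 1 has no finite
    hazard and raises ``ValueError``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if horizon_months <= 0:
        raise ValueError(f"horizon must be positive, got {horizon_months}")
    return -math.log1p(-p) / horizon_months


def rate_to_prob(r: float, horizon_months: float) -> float:
    """Convert a hazard per month to a probability over ``horizon_months``.

    ``p = 1 - exp(-r * horizon)``; inverse of :func:`prob_to_rate`.
    """
    if r < 0:
        raise ValueError(f"rate must be non-negative, got {r}")
    if horizon_months <= 0:
        raise ValueError(f"horizon must be positive, got {horizon_months}")
    return -math.expm1(-r * horizon_months)


def rescale_probability(p: float, from_months: float, to_months: float) -> float:
    """Re-express a probability from one time horizon on another.

    Goes through the constant-hazard representation, e.g. an annual risk of
    0.088 becomes a quarterly risk of ``1 - 0.912**(1/4)``.
    """
    return rate_to_prob(prob_to_rate(p, from_months), to_months)


def apply_odds_ratio(p0: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a baseline probability on the odds scale.

    Returns ``or * w / (1 + or * w)`` with ``w = p0 / (1 - p0)``; the result
    lies in [0, 1) and is strictly increasing in both arguments.
    """
    if not 0.0 <= p0 < 1.0:
        raise ValueError(f"baseline probability must be in [0, 1), got {p0}")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    w = odds_ratio * p0 / (1.0 - p0)
    return w / (1.0 + w)


_RISK_CLAMP = 1.0 - 1e-12


def apply_effect(p0: float, odds_ratio: float, scale: str = "risk") -> float:
    """Apply a treatment-effect odds ratio to a baseline risk.

    ``scale="odds"`` uses the odds-scale conversion of
    :func:`apply_odds_ratio`.  ``scale="risk"`` multiplies the baseline risk
    directly by the odds ratio (treating it as a risk ratio), which is how
    many spreadsheet decision models operate and is the default used by the
    cohort model; the product is clamped just below 1 for extreme inputs.

    Unlike :func:`apply_odds_ratio`, a baseline of exactly 1 is accepted (a
    perfect screen makes every screen-positive a future case): infinite odds
    stay infinite, so the odds-scale result is 1, and the risk-scale result
    is the odds ratio itself.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"baseline probability must be in [0, 1], got {p0}")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if scale == "odds":
        return 1.0 if p0 == 1.0 else apply_odds_ratio(p0, odds_ratio)
    if scale == "risk":
        return min(p0 * odds_ratio, _RISK_CLAMP)
    raise ValueError(f"unknown effect scale {scale!r}; expected 'risk' or 'odds'")


class TwoByTwo(NamedTuple):
    """Counts from a two-arm binary-outcome comparison."""

    events_treat: float
    n_treat: float
    events_control: float
    n_control: float


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    se_log_or: float
    continuity_corrected: bool


def odds_ratio_from_counts(table: TwoByTwo) -> OddsRatioResult:
    """Odds ratio and SE of its log from a 2x2 table.

    Standard layout a/b (treated events / non-events), c/d (control).
    Zero cells receive the Haldane–Anscombe 0.5 correction on all cells,
    flagged in the result.
    """
    a = table.events_treat
    b = table.n_treat - table.events_treat
    c = table.events_control
    d = table.n_control - table.events_control
    if min(table.n_treat, table.n_control) < 1:
        raise ValueError("each arm needs at least one subject")
    if a < 0 or b < 0 or c < 0 or d < 0:
        raise ValueError("event counts cannot exceed arm sizes or be negative")
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(or_, se, corrected)


def beta_from_mean_se(mean: float, se: float, name: str = "") -> tuple[float, float]:
    """Method-of-moments beta parameters (alpha, beta) for a given mean/SE."""
    label = f" for parameter {name!r}" if name else ""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1){label}, got {mean}")
    if se <= 0:
        raise ValueError(f"beta SE must be positive{label}, got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"beta moments infeasible{label}: se^2={var:.6g} >= mean(1-mean)="
            f"{mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_se(mean: float, se: float, name: str = "") -> tuple[float, float]:
    """Method-of-moments gamma parameters (shape, scale) for a given mean/SE."""
    label = f" for parameter {name!r}" if name else ""
    if mean <= 0 or se <= 0:
        raise ValueError(f"gamma mean and SE must be positive{label}")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def lognormal_from_or_ci(
    or_: float, ci_low: float, ci_high: float, name: str = ""
) -> tuple[float, float]:
    """Log-normal (mu, sigma) for an odds ratio with a 95% CI.

    ``mu = ln(or)`` (the OR is the distribution's median) and
    ``sigma = (ln(hi) - ln(lo)) / (2 * 1.96)``.
    """
    label = f" for parameter {name!r}" if name else ""
    if not 0.0 < ci_low < or_ < ci_high:
        raise ValueError(
            f"require 0 < ci_low < or < ci_high{label}, got ({ci_low}, {or_}, {ci_high})"
        )
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2.0 * 1.959963984540054)
    return math.log(or_), sigma


def lognormal_from_or_se(or_: float, se: float, name: str = "") -> tuple[float, float]:
    """Log-normal (mu, sigma) for an odds ratio with an SE on the OR scale.

    Delta-method approximation ``sigma = se / or``; used only when no CI is
    available.
    """
    label = f" for parameter {name!r}" if name else ""
    if or_ <= 0 or se <= 0:
        raise ValueError(f"odds ratio and SE must be positive{label}")
    return math.log(or_), se / or_
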