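"""Prevalences, relative risks, odds ratios and credible-interval summaries.

Risk quantities compare the neutered class of a sex with its intact
counterpart: ``RR_F = p_NF / p_F``, ``RR_M = p_NM / p_M``, and the
corresponding odds ratios ``OR = [p_N/(1-p_N)] / [p_I/(1-p_I)]``.  Ratios
are evaluated draw-by-draw from posterior samples and then summarized
(posterior mean, posterior SD, equal-tailed 95% credible interval); a
quantity is flagged significant when its interval excludes 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data_ingest import CountTable, SexClass
from .hier_model import PosteriorDraws

__all__ = [
    "QUANTITIES",
    "RiskEstimate",
    "CrudeEstimate",
    "PredictedProbability",
    "prevalence",
    "posterior_ratio",
    "crude_ratio",
    "predicted_probability",
    "ZeroCellError",
]

#: Supported ratio quantities: (name) -> (numerator class, denominator class)
QUANTITY_PAIRS = {
    "RR_F": (SexClass.NF, SexClass.F),
    "OR_F": (SexClass.NF, SexClass.F),
    "RR_M": (SexClass.NM, SexClass.M),
    "OR_M": (SexClass.NM, SexClass.M),
}
QUANTITIES = tuple(QUANTITY_PAIRS)


class ZeroCellError(ValueError):
    """A crude ratio is undefined because of an empty contingency cell."""


def prevalence(cases: int, total: int) -> float:
    """Disease prevalence: affected count over the category denominator."""
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not 0 <= cases <= total:
        raise ValueError(f"need 0 <= cases <= total, got {cases}/{total}")
    return cases / total


@dataclass(frozen=True)
class RiskEstimate:
    """Posterior summary of one RR or OR.

    ``applicable`` is False when the table lacks the class pair (the male
    quantities of pyometra); numeric fields are then ``nan``.
    """

    quantity: str
    point: float
    sd: float
    ci_low: float
    ci_high: float
    significant: bool
    n_draws: int
    applicable: bool = True

    @classmethod
    def not_applicable(cls, quantity: str) -> "RiskEstimate":
        nan = float("nan")
        return cls(quantity, nan, nan, nan, nan, False, 0, applicable=False)

    def __str__(self) -> str:
        if not self.applicable:
            return "NA"
        star = "*" if self.significant else ""
        return f"{self.point:.2f} ± {self.sd:.2f}{star}"


@dataclass(frozen=True)
class PredictedProbability:
    """Posterior mean and equal-tailed 95% interval of one class probability."""

    sex_class: SexClass
    mean: float
    ci_low: float
    ci_high: float


def posterior_ratio(draws: PosteriorDraws, quantity: str) -> RiskEstimate:
    """Summarize one risk quantity from posterior draws.

    The ratio is formed draw-by-draw (posterior mean *of the ratio*, not a
    ratio of posterior means), so the full uncertainty of both classes,
    including their skew, propagates into the summary.
    """
    if quantity not in QUANTITY_PAIRS:
        raise KeyError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")
    num_cls, den_cls = QUANTITY_PAIRS[quantity]
    if num_cls not in draws.classes or den_cls not in draws.classes:
        return RiskEstimate.not_applicable(quantity)
    p_num = draws.prob(num_cls).ravel()
    p_den = draws.prob(den_cls).ravel()
    if quantity.startswith("OR"):
        ratio = (p_num / (1.0 - p_num)) / (p_den / (1.0 - p_den))
    else:
        ratio = p_num / p_den
    point = float(ratio.mean())
    sd = float(ratio.std(ddof=1)) if ratio.size > 1 else 0.0
    lo, hi = (float(q) for q in np.quantile(ratio, [0.025, 0.975]))
    significant = bool(lo > 1.0 or hi < 1.0)
    return RiskEstimate(quantity, point, sd, lo, hi, significant, ratio.size)


@dataclass(frozen=True)
class CrudeEstimate:
    """Plug-in ratio of raw proportions/odds with a log-scale Wald 95% CI."""

    quantity: str
    point: float
    ci_low: float
    ci_high: float


def crude_ratio(table: CountTable, quantity: str, level: float = 0.95) -> CrudeEstimate:
    """Frequentist baseline: crude RR/OR with a log-scale Wald interval.

    Requires non-degenerate cells; zero cells make the Wald interval
    undefined, in which case the hierarchical Bayesian estimator is the
    appropriate tool.
    """
    if quantity not in QUANTITY_PAIRS:
        raise KeyError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")
    num_cls, den_cls = QUANTITY_PAIRS[quantity]
    for c in (num_cls, den_cls):
        if c not in table.classes:
            raise ValueError(f"{table.disease}: class {c.value} unavailable")
    a, n1 = table.cases[num_cls], table.totals[num_cls]
    b, n0 = table.cases[den_cls], table.totals[den_cls]
    if a == 0 or b == 0 or a == n1 or b == n0:
        raise ZeroCellError(
            f"{table.disease}/{quantity}: degenerate cell; "
            "use the Bayesian posterior_ratio estimator"
        )
    if quantity.startswith("OR"):
        point = (a / (n1 - a)) / (b / (n0 - b))
        se = math.sqrt(1 / a + 1 / (n1 - a) + 1 / b + 1 / (n0 - b))
    else:
        point = (a / n1) / (b / n0)
        se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n0)
    z = norm.ppf(0.5 + level / 2.0)
    return CrudeEstimate(
        quantity, point, point * math.exp(-z * se), point * math.exp(z * se)
    )


def predicted_probability(draws: PosteriorDraws, sex_class: SexClass) -> PredictedProbability:
    """Caterpillar-plot coordinates: posterior mean and 95% CI of one p_i."""
    if sex_class not in draws.classes:
        raise ValueError(f"{draws.disease}: class {sex_class.value} unavailable")
    p = draws.prob(sex_class).ravel()
    lo, hi = (float(q) for q in np.quantile(p, [0.025, 0.975]))
    return PredictedProbability(sex_class, float(p.mean()), lo, hi)
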