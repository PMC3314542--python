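"""Shared statistical primitives: proportions, Wald/Wilson CIs, chi-square.

These back the reporting layer (and the capture-recapture percentage
transform). The Wald interval uses z = 1.96 in closed form — with the large
denominators in scope it is indistinguishable from better intervals and it
is the form that administrative birth reports print.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats as sps

from .exceptions import UndefinedMetricError, ValidationError

Z95 = 1.96


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (printed-table convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionEstimate:
    """A count over a denominator with a 95% CI, on the percent scale.

    ``pct``, ``ci_low`` and ``ci_high`` are kept at full precision; apply
    :func:`round_half_up` when formatting tables.
    """

    count: float
    denominator: int
    pct: float
    ci_low: float
    ci_high: float

    def rounded(self, ndigits: int = 2) -> tuple:
        return (
            round_half_up(self.pct, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


def proportion_ci(count: float, denominator: int, method: str = "wald") -> ProportionEstimate:
    """Percentage of ``count / denominator`` with a 95% CI, clipped to [0, 100]."""
    if denominator <= 0:
        raise UndefinedMetricError("proportion undefined: zero denominator")
    if not 0 <= count <= denominator:
        raise ValidationError(f"count {count} outside [0, {denominator}]")
    p = count / denominator
    if method == "wald":
        half = Z95 * np.sqrt(p * (1.0 - p) / denominator)
        lo, hi = p - half, p + half
    elif method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(count, denominator, alpha=0.05, method="wilson")
    else:
        raise ValidationError(f"unknown CI method: {method!r}")
    return ProportionEstimate(
        count=count,
        denominator=denominator,
        pct=100.0 * p,
        ci_low=float(np.clip(100.0 * lo, 0.0, 100.0)),
        ci_high=float(np.clip(100.0 * hi, 0.0, 100.0)),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Pearson chi-square comparison of two proportions (df = 1)."""

    statistic: float
    df: int
    p_value: float
    significant: bool  # at alpha = 0.05


def chi_square_two_props(a: int, n_a: int, b: int, n_b: int) -> ComparisonResult:
    """Two-proportion Pearson chi-square without continuity correction.

    Compares a/n_a against b/n_b via the 2x2 table [[a, n_a-a], [b, n_b-b]];
    statistic is n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    if not (0 <= a <= n_a and 0 <= b <= n_b):
        raise ValidationError("cell counts outside their margins")
    c, d = n_a - a, n_b - b
    n = n_a + n_b
    col1, col2 = a + b, c + d
    if n_a == 0 or n_b == 0 or col1 == 0 or col2 == 0:
        raise UndefinedMetricError("chi-square undefined: empty margin")
    stat = n * (a * d - b * c) ** 2 / (n_a * n_b * col1 * col2)
    p = float(sps.chi2.sf(stat, df=1))
    return ComparisonResult(statistic=float(stat), df=1, p_value=p, significant=p < 0.05)


def union_total(n_source1: int, n_source2: int, n_linked: int) -> int:
    """Distinct entities across two sources given their overlap."""
    if n_linked > min(n_source1, n_source2) or min(n_source1, n_source2, n_linked) < 0:
        raise ValidationError("overlap exceeds a source total")
    return n_source1 + n_source2 - n_linked
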