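"""Agreement-based data-quality metrics on linked, both-stated births.

With no gold standard available, each collection serves in turn as the
reference for the other, so the sensitivities and specificities computed
here are *relative*: they measure agreement structure, not accuracy against
truth. The 2x2 table cross-classifies the collapsed statuses:

              RBDM Indigenous   RBDM non-Indigenous
MDC Indig.          A                   B
MDC non-I.          C                   D
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import UndefinedMetricError, ValidationError
from .records import INDIGENOUS, NOT_STATED, collapse_series


@dataclass(frozen=True)
class TwoByTwo:
    a: int  # Indigenous in both
    b: int  # MDC Indigenous, RBDM non-Indigenous
    c: int  # MDC non-Indigenous, RBDM Indigenous
    d: int  # non-Indigenous in both

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 counts must be nonnegative")

    @property
    def t(self) -> int:
        return self.a + self.b + self.c + self.d


def both_stated(linked: pd.DataFrame) -> pd.DataFrame:
    """Linked births with the status stated in both sources."""
    keep = (linked["mdc_status"] != NOT_STATED) & (linked["rbdm_status"] != NOT_STATED)
    return linked[keep]


def build_two_by_two(linked: pd.DataFrame) -> TwoByTwo:
    """Cross-classify collapsed statuses of linked, both-stated births."""
    m = collapse_series(linked["mdc_status"])
    r = collapse_series(linked["rbdm_status"])
    if (m == NOT_STATED).any() or (r == NOT_STATED).any():
        raise ValidationError("not-stated records present; exclude them first")
    mi, ri = m == INDIGENOUS, r == INDIGENOUS
    return TwoByTwo(
        a=int((mi & ri).sum()),
        b=int((mi & ~ri).sum()),
        c=int((~mi & ri).sum()),
        d=int((~mi & ~ri).sum()),
    )


def consistency(t: TwoByTwo) -> float:
    """Percentage of linked births where the two sources agree: 100(A+D)/T."""
    if t.t == 0:
        raise UndefinedMetricError("consistency undefined: empty table")
    return 100.0 * (t.a + t.d) / t.t


def sensitivities(t: TwoByTwo) -> tuple[float, float]:
    """Relative sensitivities (sens_mdc, sens_rbdm) = (A/(A+C), A/(A+B)) x100.

    Each source's sensitivity treats the other source's report as the
    reference standard.
    """
    if t.a + t.c == 0:
        raise UndefinedMetricError("sens_mdc undefined: no RBDM-identified Indigenous births")
    if t.a + t.b == 0:
        raise UndefinedMetricError("sens_rbdm undefined: no MDC-identified Indigenous births")
    return 100.0 * t.a / (t.a + t.c), 100.0 * t.a / (t.a + t.b)


def specificities(t: TwoByTwo) -> tuple[float, float]:
    """Relative specificities (spec_mdc, spec_rbdm) = (D/(B+D), D/(C+D)) x100."""
    if t.b + t.d == 0:
        raise UndefinedMetricError("spec_mdc undefined: no RBDM non-Indigenous births")
    if t.c + t.d == 0:
        raise UndefinedMetricError("spec_rbdm undefined: no MDC non-Indigenous births")
    return 100.0 * t.d / (t.b + t.d), 100.0 * t.d / (t.c + t.d)


def completeness(stated: int, total: int) -> float:
    """Percentage of records with a stated (non-missing) status."""
    if total <= 0:
        raise UndefinedMetricError("completeness undefined: zero total")
    if not 0 <= stated <= total:
        raise ValidationError("stated count outside [0, total]")
    return 100.0 * stated / total
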