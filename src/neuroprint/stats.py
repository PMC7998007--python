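"""Contingency statistics for the simulated clinical validation.

Respondents' planning decisions before/after inspecting the printed model
are tallied into 2x2 tables (respondent group x changed/unchanged) and
tested with Fisher's exact test — computed here by direct hypergeometric
enumeration over all tables with the observed margins — and the classical
chi-square test for a 2x2 table. Percentages are reported to one decimal,
rounded half-up at display time only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import chi2, hypergeom

from .errors import ParameterError

__all__ = ["ContingencyTable2x2", "TestResult", "fisher_exact", "chi_square", "change_rate", "likert_means"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows are respondent groups, columns changed/unchanged.

    ::

                changed  unchanged
        group1     a         b
        group2     c         d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("counts must be nonnegative")
        if self.total == 0:
            raise ParameterError("table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    statistic: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError("p-value outside [0, 1]")


def _support(table: ContingencyTable2x2):
    """Hypergeometric model of cell `a` under fixed margins."""
    r1, _, c1, _ = table.margins
    n = table.total
    rv = hypergeom(n, c1, r1)  # population n, c1 'changed', draw r1 (group 1)
    a_min = max(0, r1 + c1 - n)
    a_max = min(r1, c1)
    return rv, a_min, a_max


def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> TestResult:
    """Fisher's exact test by hypergeometric enumeration.

    ``one``-sided sums the upper tail from the observed ``a`` (more changes
    in group 1 than independence predicts); ``two``-sided sums every table
    whose probability does not exceed the observed table's.
    """
    rv, a_min, a_max = _support(table)
    support = np.arange(a_min, a_max + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(table.a)
    if sided == "one":
        p = float(pmf[support >= table.a].sum())
        method = "fisher_one_sided"
    elif sided == "two":
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
        method = "fisher_two_sided"
    else:
        raise ParameterError("sided must be 'one' or 'two'")
    return TestResult(p_value=min(p, 1.0), method=method)


def chi_square(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Chi-square test of independence for a 2x2 table (1 df).

    statistic = N (|ad - bc| - N/2 if Yates) ^2 / (r1 r2 c1 c2).
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ParameterError("a zero margin leaves no test to run")
    n = table.total
    det = abs(table.a * table.d - table.b * table.c)
    if yates:
        det = max(0.0, det - n / 2.0)
    stat = n * det ** 2 / (r1 * r2 * c1 * c2)
    p = float(chi2.sf(stat, df=1))
    return TestResult(p_value=p, statistic=float(stat),
                      method="chi_square_yates" if yates else "chi_square")


def change_rate(changed: int, total: int) -> float:
    """Percent of decisions changed, to one decimal (half-up)."""
    if total <= 0:
        raise ParameterError("total must be > 0")
    if not (0 <= changed <= total):
        raise ParameterError("changed must lie in [0, total]")
    pct = Decimal(100 * changed) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def likert_means(responses: dict[str, list[float]]) -> dict[str, float]:
    """Plain per-question means of 1-5 ratings (no inferential claim)."""
    out = {}
    for question, values in responses.items():
        arr = np.asarray(values, float)
        if arr.size == 0 or arr.min() < 1 or arr.max() > 5:
            raise ParameterError(f"ratings for {question!r} must be in [1, 5]")
        out[question] = float(arr.mean())
    return out
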