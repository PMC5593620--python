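"""Per-stratum reporting odds ratios and cohort-level association tests.

The reporting odds ratio (ROR) for a 2x2 table of drug exposure x event
reporting is (a*d)/(b*c); values above 1 indicate disproportionate
reporting of the event under the index drug.  Confidence intervals use the
Woolf (log) method.  Tables with a zero cell receive the Haldane–Anscombe
correction: 0.5 added to all four cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import stats

from .report_store import ContingencyTable2x2

__all__ = [
    "AssociationTest",
    "DegenerateTableError",
    "EffectEstimate",
    "aggregate_tables",
    "g_test",
    "pearson_chi2",
    "ror",
]


class DegenerateTableError(ValueError):
    """A margin of the table is zero, so the statistic is undefined."""


@dataclass(frozen=True)
class EffectEstimate:
    """Log reporting odds ratio for one stratum with Woolf variance."""

    stratum: str
    log_ror: float
    variance: float
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class AssociationTest:
    """A chi-square-distributed test of independence on a 2x2 table."""

    statistic: float
    df: int
    p_value: float
    kind: Literal["pearson_chi2", "g_test"]


def _corrected_cells(table: ContingencyTable2x2) -> tuple[tuple[float, float, float, float], bool]:
    if table.n == 0:
        raise DegenerateTableError("table has no reports (n = 0)")
    a, b, c, d = table.cells
    if min(a, b, c, d) == 0:
        return (a + 0.5, b + 0.5, c + 0.5, d + 0.5), True
    return (float(a), float(b), float(c), float(d)), False


def ror(table: ContingencyTable2x2, ci_level: float = 0.95) -> EffectEstimate:
    """Reporting odds ratio with Woolf confidence interval.

    If any cell is zero, 0.5 is first added to all four cells
    (Haldane–Anscombe) and the result is flagged ``corrected``.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    (a, b, c, d), corrected = _corrected_cells(table)
    log_ror = math.log(a * d) - math.log(b * c)
    variance = 1 / a + 1 / b + 1 / c + 1 / d
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * math.sqrt(variance)
    return EffectEstimate(
        stratum=table.stratum,
        log_ror=log_ror,
        variance=variance,
        ror=math.exp(log_ror),
        ci_low=math.exp(log_ror - half),
        ci_high=math.exp(log_ror + half),
        corrected=corrected,
    )


def pearson_chi2(table: ContingencyTable2x2) -> AssociationTest:
    """Pearson chi-square test of independence, no Yates correction.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    a, b, c, d = table.cells
    n = table.n
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        raise DegenerateTableError("degenerate table: a margin is zero")
    statistic = n * (a * d - b * c) ** 2 / math.prod(margins)
    return AssociationTest(statistic, 1, float(stats.chi2.sf(statistic, 1)), "pearson_chi2")


def g_test(table: ContingencyTable2x2) -> AssociationTest:
    """Likelihood-ratio (G) test of independence: G = 2 * sum O ln(O/E).

    A zero observed cell triggers the same +0.5 all-cells correction used
    for the ROR before expected counts are formed.
    """
    (a, b, c, d), _ = _corrected_cells(table)
    n = a + b + c + d
    observed = ((a, b), (c, d))
    row = (a + b, c + d)
    col = (a + c, b + d)
    g = 0.0
    for i in range(2):
        for j in range(2):
            expected = row[i] * col[j] / n
            g += observed[i][j] * math.log(observed[i][j] / expected)
    g *= 2
    return AssociationTest(g, 1, float(stats.chi2.sf(g, 1)), "g_test")


def aggregate_tables(
    tables: Sequence[ContingencyTable2x2], stratum: str = "all"
) -> ContingencyTable2x2:
    """Cell-wise sum of per-stratum tables (whole-cohort table)."""
    if not tables:
        raise ValueError("no tables to aggregate")
    return ContingencyTable2x2(
        stratum,
        sum(t.a for t in tables),
        sum(t.b for t in tables),
        sum(t.c for t in tables),
        sum(t.d for t in tables),
    )
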