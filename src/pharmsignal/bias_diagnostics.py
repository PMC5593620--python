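"""Reporting-bias diagnostics: Egger regression, funnel data, leave-one-out.

Egger's test regresses the standardized effect z_i = y_i / se_i on the
precision 1/se_i by ordinary least squares; a non-zero intercept indicates
funnel-plot asymmetry (small strata drifting from the pooled effect).  The
leave-one-out sensitivity analysis re-pools after omitting each stratum in
turn, keeping the model selected on the full data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .disproportionality import EffectEstimate, ror
from .meta_pool import (
    FIXED_MH,
    RANDOM_DL,
    ModelTag,
    PooledResult,
    heterogeneity,
    pool_fixed_mh,
    pool_random_dl,
)
from .report_store import ContingencyTable2x2

__all__ = [
    "EggerResult",
    "LeaveOneOutResult",
    "SensitivityEntry",
    "egger_test",
    "funnel_data",
    "leave_one_out",
]


@dataclass(frozen=True)
class EggerResult:
    """Intercept test of the standardized-effect-on-precision regression."""

    intercept: float
    se_intercept: float
    t_stat: float
    df: int
    p_value: float
    slope: float


@dataclass(frozen=True)
class SensitivityEntry:
    omitted_stratum: str
    result: PooledResult


@dataclass(frozen=True)
class LeaveOneOutResult:
    entries: tuple[SensitivityEntry, ...]
    min_ror: float
    max_ror: float
    min_ci_low: float


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear regression test for funnel-plot asymmetry.

    Two-sided Student t test of the intercept at k-2 degrees of freedom.
    When the regression fits exactly (zero residual), the intercept's
    standard error vanishes; an intercept at 0 then yields t = 0, p = 1.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("insufficient strata")
    se = np.array([e.se for e in effects])
    y = np.array([e.log_ror for e in effects])
    precision = 1 / se
    if np.ptp(precision) < 1e-12:
        raise ValueError("precision has no variation")

    design = sm.add_constant(precision)
    fit = sm.OLS(y / se, design).fit()
    intercept = float(fit.params[0])
    se_intercept = float(fit.bse[0])
    df = k - 2

    if not math.isfinite(se_intercept) or se_intercept < 1e-12:
        # exact fit: degenerate t; sign decided by whether the intercept is 0
        if abs(intercept) < 1e-10:
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = math.copysign(math.inf, intercept), 0.0
    else:
        t_stat = float(fit.tvalues[0])
        p_value = float(fit.pvalues[0])
    return EggerResult(
        intercept=intercept,
        se_intercept=se_intercept,
        t_stat=t_stat,
        df=df,
        p_value=p_value,
        slope=float(fit.params[1]),
    )


def funnel_data(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Per-stratum (log effect, standard error) table for funnel plotting."""
    if not effects:
        raise ValueError("need >=1 stratum")
    return pd.DataFrame(
        {
            "stratum": [e.stratum for e in effects],
            "log_ror": [e.log_ror for e in effects],
            "se": [e.se for e in effects],
        }
    )


def _pool(tables: Sequence[ContingencyTable2x2], model: ModelTag, ci_level: float) -> PooledResult:
    if model == FIXED_MH:
        return pool_fixed_mh(tables, ci_level=ci_level)
    if model == RANDOM_DL:
        effects = [ror(t, ci_level=ci_level) for t in tables]
        return pool_random_dl(effects, heterogeneity(effects), ci_level=ci_level)
    raise ValueError(f"unknown model tag {model!r}")


def leave_one_out(
    tables: Sequence[ContingencyTable2x2],
    model: ModelTag,
    ci_level: float = 0.95,
) -> LeaveOneOutResult:
    """Re-pool with each stratum omitted in turn, under a fixed model choice.

    The model selected on the full data is applied to every subset (it is
    not re-selected); for the random-effects model tau^2 is re-estimated on
    each subset.  Returns the per-omission pooled results in stratum order
    plus the min/max pooled ROR and the smallest lower confidence bound.
    """
    if len(tables) < 3:
        raise ValueError("need >=3 strata")
    entries = []
    for i, omitted in enumerate(tables):
        subset = [t for j, t in enumerate(tables) if j != i]
        entries.append(SensitivityEntry(omitted.stratum, _pool(subset, model, ci_level)))
    rors = [e.result.pooled_ror for e in entries]
    return LeaveOneOutResult(
        entries=tuple(entries),
        min_ror=min(rors),
        max_ror=max(rors),
        min_ci_low=min(e.result.ci_low for e in entries),
    )
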