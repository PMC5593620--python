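"""Between-year heterogeneity and pooled reporting odds ratios.

Per-year log RORs y_i with Woolf variances v_i are combined either under a
fixed-effects model — the Mantel-Haenszel pooled odds ratio computed from
the raw stratified cell counts, with the Robins–Breslow–Greenland (RBG)
variance for its log — or under the DerSimonian-Laird random-effects model,
which inflates each v_i by a moments estimate of the between-year variance
tau^2.  Cochran's Q (inverse-variance weights) drives both the I^2
heterogeneity percentage and the model-selection rule: random effects when
the Q test is significant, fixed effects otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import stats

from .disproportionality import EffectEstimate
from .report_store import ContingencyTable2x2

__all__ = [
    "FIXED_MH",
    "HeterogeneityResult",
    "PooledResult",
    "RANDOM_DL",
    "heterogeneity",
    "pool_fixed_mh",
    "pool_random_dl",
    "select_model",
]

FIXED_MH: Literal["fixed_mh"] = "fixed_mh"
RANDOM_DL: Literal["random_dl"] = "random_dl"

ModelTag = Literal["fixed_mh", "random_dl"]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value, I^2 and DL tau^2."""

    Q: float
    df: int
    p_value: float
    I2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    """Pooled log ROR with Wald z-test on the log scale."""

    model: ModelTag
    pooled_log: float
    se: float
    pooled_ror: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    k: int
    tau2: float


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q test across strata with I^2 and the DL tau^2 estimate.

    Q = sum w_i (y_i - yhat)^2 with w_i = 1/v_i and yhat the
    inverse-variance-weighted mean; I^2 = 100 (Q - df)/Q floored at 0;
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    """
    k = len(effects)
    if k < 2:
        raise ValueError("need >=2 strata")
    if any(e.variance <= 0 for e in effects):
        raise ValueError("all variances must be positive")

    w = [1 / e.variance for e in effects]
    sw = sum(w)
    yhat = sum(wi * e.log_ror for wi, e in zip(w, effects)) / sw
    Q = sum(wi * (e.log_ror - yhat) ** 2 for wi, e in zip(w, effects))
    df = k - 1
    p = float(stats.chi2.sf(Q, df))
    I2 = 0.0 if Q <= 0 else max(0.0, 100.0 * (Q - df) / Q)
    denom = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, p_value=p, I2=I2, tau2=tau2)


def _wald(pooled_log: float, se: float, ci_level: float) -> tuple[float, float, float, float]:
    z_crit = stats.norm.ppf(0.5 + ci_level / 2)
    z = pooled_log / se
    p = float(2 * stats.norm.sf(abs(z)))
    return math.exp(pooled_log - z_crit * se), math.exp(pooled_log + z_crit * se), z, p


def pool_fixed_mh(
    tables: Sequence[ContingencyTable2x2], ci_level: float = 0.95
) -> PooledResult:
    """Mantel-Haenszel fixed-effects pooled odds ratio.

    Point estimate sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the variance of
    its log is the Robins–Breslow–Greenland estimator.  Raw cell counts are
    used without continuity correction (zero cells contribute zero weight).
    """
    if not tables:
        raise ValueError("need >=1 stratum")
    R = sum(t.a * t.d / t.n for t in tables)
    S = sum(t.b * t.c / t.n for t in tables)
    if S == 0:
        raise ValueError("no unexposed events")
    if R == 0:
        raise ValueError("no exposed events")
    pooled_log = math.log(R / S)

    sum_PR = sum((t.a + t.d) / t.n * (t.a * t.d / t.n) for t in tables)
    sum_PSQR = sum(
        (t.a + t.d) / t.n * (t.b * t.c / t.n) + (t.b + t.c) / t.n * (t.a * t.d / t.n)
        for t in tables
    )
    sum_QS = sum((t.b + t.c) / t.n * (t.b * t.c / t.n) for t in tables)
    variance = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    se = math.sqrt(variance)

    ci_low, ci_high, z, p = _wald(pooled_log, se, ci_level)
    return PooledResult(
        model=FIXED_MH,
        pooled_log=pooled_log,
        se=se,
        pooled_ror=R / S,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        p_value=p,
        k=len(tables),
        tau2=0.0,
    )


def pool_random_dl(
    effects: Sequence[EffectEstimate],
    het: HeterogeneityResult | None = None,
    ci_level: float = 0.95,
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling of per-stratum log RORs.

    Weights are 1/(v_i + tau^2) with tau^2 from ``het`` (recomputed when not
    supplied).  With tau^2 = 0 this reduces to inverse-variance fixed
    pooling.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("need >=2 strata")
    if het is None:
        het = heterogeneity(effects)
    elif het.df != k - 1:
        raise ValueError(
            f"mismatched inputs: heterogeneity df={het.df} implies {het.df + 1} strata, got {k}"
        )

    w = [1 / (e.variance + het.tau2) for e in effects]
    sw = sum(w)
    pooled_log = sum(wi * e.log_ror for wi, e in zip(w, effects)) / sw
    se = 1 / math.sqrt(sw)
    ci_low, ci_high, z, p = _wald(pooled_log, se, ci_level)
    return PooledResult(
        model=RANDOM_DL,
        pooled_log=pooled_log,
        se=se,
        pooled_ror=math.exp(pooled_log),
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        p_value=p,
        k=k,
        tau2=het.tau2,
    )


def select_model(het: HeterogeneityResult, alpha: float = 0.05) -> ModelTag:
    """Random effects when the Q test is significant, fixed effects otherwise."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return RANDOM_DL if het.p_value < alpha else FIXED_MH
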