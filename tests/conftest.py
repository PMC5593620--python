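import math

import pytest

from pharmsignal import AdverseEventReport, ContingencyTable2x2, DrugEntry, EffectEstimate


def make_effect(y: float, v: float, stratum: str = "s") -> EffectEstimate:
    """Effect estimate with given log ROR and variance (CI fields unused)."""
    half = 1.959964 * math.sqrt(v)
    return EffectEstimate(
        stratum=stratum,
        log_ror=y,
        variance=v,
        ror=math.exp(y),
        ci_low=math.exp(y - half),
        ci_high=math.exp(y + half),
        corrected=False,
    )


def make_report(report_id, year, drug, indication, reaction):
    return AdverseEventReport(
        report_id=report_id,
        receipt_year=year,
        drugs=(DrugEntry(drug.upper(), indication.upper() if indication else None),),
        reactions=(reaction.upper(),),
    )


@pytest.fixture
def worked_effects():
    """Three equal-variance strata with evenly spaced log effects."""
    return [make_effect(y, 0.04, s) for y, s in [(0.0, "2004"), (0.5, "2005"), (1.0, "2006")]]


@pytest.fixture
def two_tables():
    return [
        ContingencyTable2x2("2004", 10, 90, 10, 90),
        ContingencyTable2x2("2005", 20, 80, 10, 90),
    ]
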