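"""Seeded generators for FAERS-like study data with known ground truth.

The yearly-table generator realizes the data-generating process the
random-effects analysis assumes: each year's true log odds ratio is drawn
from Normal(theta, tau^2); every report is independently exposed to the
index drug with probability ``p_exposed``; the event probability is
``p_event0`` for unexposed reports and logit-shifted by the year effect for
exposed reports.  The report-level generator expands the same counts into
individual case reports, so tabulating its output reproduces the tables
cell-for-cell.

Default parameters mirror the shape of the atrial-fibrillation digoxin
cohort: 12 report years (2004-2015), an exposed fraction near 0.108
(8142 of 75618 reports) and a pooled reporting odds ratio near 1.38.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .dgi_network import GeneSet
from .report_store import AdverseEventReport, ContingencyTable2x2, DrugEntry

__all__ = [
    "INDEX_DRUG",
    "INDEX_INDICATION",
    "INDEX_REACTION",
    "SimulationTruth",
    "simulate_gene_universe",
    "simulate_reports",
    "simulate_yearly_tables",
]

INDEX_DRUG = "DIGOXIN"
INDEX_REACTION = "ANAEMIA"
INDEX_INDICATION = "ATRIAL FIBRILLATION"
_CONTROL_DRUG = "OTHER THERAPY"
_CONTROL_REACTION = "NAUSEA"


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of a simulated reporting cohort.

    theta
        True log odds ratio linking exposure to the event.
    tau2
        Between-year variance of the year-level log odds ratio.
    p_event0
        Baseline event probability among unexposed reports.
    p_exposed
        Probability that a report lists the index drug.
    n_per_year
        Reports per study year.
    years
        Year labels, one stratum each.
    seed
        RNG seed; every stochastic operation is reproducible from it.
    """

    seed: int
    theta: float = math.log(1.38)
    tau2: float = 0.05
    p_event0: float = 0.02
    p_exposed: float = 0.108
    n_per_year: int = 6300
    years: tuple[int, ...] = tuple(range(2004, 2016))

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not 0 < self.p_event0 < 1 or not 0 < self.p_exposed < 1:
            raise ValueError("probabilities must lie in (0, 1)")
        if self.n_per_year < 1:
            raise ValueError("n_per_year must be >= 1")
        if not self.years:
            raise ValueError("years must be non-empty")


def simulate_yearly_tables(
    truth: SimulationTruth,
) -> tuple[list[ContingencyTable2x2], SimulationTruth]:
    """Draw one 2x2 table per study year under ``truth``.

    Emits a warning when the smallest expected cell falls below 1 (the
    resulting tables will frequently need continuity correction).
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_per_year
    p0 = truth.p_event0
    p1_center = expit(logit(p0) + truth.theta)
    expected_min = n * min(
        truth.p_exposed * p1_center,
        truth.p_exposed * (1 - p1_center),
        (1 - truth.p_exposed) * p0,
        (1 - truth.p_exposed) * (1 - p0),
    )
    if expected_min < 1:
        warnings.warn(
            f"expected minimum cell count {expected_min:.2f} < 1; "
            "tables will be sparse",
            stacklevel=2,
        )

    tables = []
    for year in truth.years:
        theta_i = rng.normal(truth.theta, math.sqrt(truth.tau2))
        p1 = expit(logit(p0) + theta_i)
        n_exposed = int(rng.binomial(n, truth.p_exposed))
        a = int(rng.binomial(n_exposed, p1)) if n_exposed else 0
        c = int(rng.binomial(n - n_exposed, p0)) if n_exposed < n else 0
        tables.append(
            ContingencyTable2x2(str(year), a, n_exposed - a, c, n - n_exposed - c)
        )
    return tables, truth


def simulate_reports(
    truth: SimulationTruth,
    drug_term: str = INDEX_DRUG,
    reaction_term: str = INDEX_REACTION,
    indication_term: str = INDEX_INDICATION,
) -> list[AdverseEventReport]:
    """Expand the simulated yearly counts into individual case reports.

    The same seed yields exactly the counts of
    :func:`simulate_yearly_tables`: exposed reports list the index drug,
    event reports the index reaction, and every report carries the index
    indication, so re-tabulating the output reproduces the tables
    cell-for-cell.  Report ids are unique.
    """
    tables, _ = simulate_yearly_tables(truth)
    reports = []
    for table in tables:
        year = int(table.stratum)
        cells = (
            (table.a, True, True),
            (table.b, True, False),
            (table.c, False, True),
            (table.d, False, False),
        )
        serial = 0
        for count, exposed, event in cells:
            for _ in range(count):
                serial += 1
                product = drug_term if exposed else _CONTROL_DRUG
                reaction = reaction_term if event else _CONTROL_REACTION
                reports.append(
                    AdverseEventReport(
                        report_id=f"SIM-{year}-{serial:07d}",
                        receipt_year=year,
                        drugs=(DrugEntry(product.upper(), indication_term.upper()),),
                        reactions=(reaction.upper(),),
                    )
                )
    return reports


def simulate_gene_universe(
    N: int,
    n_sets: int,
    set_size: tuple[int, int],
    query_size: int,
    enriched_set_overlap: int,
    seed: int,
) -> tuple[set[str], list[GeneSet], list[str]]:
    """Build a gene background, a set collection and a query gene list.

    One designated set (``SET0000``) is forced to share exactly
    ``enriched_set_overlap`` genes with the query; the remaining sets are
    sampled uniformly from the background, so under ``overlap = 0`` the
    collection behaves as a null.

    Returns ``(background, collection, query)``; the designated set is the
    first element of the collection.
    """
    lo, hi = set_size
    if not 1 <= lo <= hi <= N:
        raise ValueError("set_size range must satisfy 1 <= lo <= hi <= N")
    if not 1 <= query_size <= N:
        raise ValueError("query_size must be in [1, N]")
    if enriched_set_overlap < 0 or enriched_set_overlap > min(query_size, hi):
        raise ValueError(
            f"infeasible overlap {enriched_set_overlap} for query_size={query_size}, "
            f"max set size {hi}"
        )

    rng = np.random.default_rng(seed)
    width = len(str(N))
    background = [f"G{i:0{width}d}" for i in range(1, N + 1)]
    bg_array = np.array(background)

    query = list(rng.choice(bg_array, size=query_size, replace=False))

    collection = []
    for idx in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if idx == 0:
            size = max(size, enriched_set_overlap)
            forced = list(rng.choice(query, size=enriched_set_overlap, replace=False))
            outside = np.array(sorted(set(background) - set(query)))
            filler = list(
                rng.choice(outside, size=min(size - enriched_set_overlap, outside.size),
                           replace=False)
            )
            members = frozenset(forced + filler)
        else:
            members = frozenset(rng.choice(bg_array, size=size, replace=False))
        collection.append(GeneSet(f"SET{idx:04d}", f"synthetic set {idx}", members))
    return set(background), collection, query
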