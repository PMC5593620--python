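"""Ingestion of spontaneous adverse-event reports and reduction to 2x2 tables.

Reports follow the openFDA drug-event schema (one JSON object per line):
``safetyreportid``, ``receiptdate``, ``patient.drug[].medicinalproduct``,
``patient.drug[].drugindication``, ``patient.reaction[].reactionmeddrapt``.
A report qualifies for a cohort when any of its drugs carries the index
indication; it is "exposed" when the index drug appears among its products
and an "event" when the index reaction appears among its reactions.  Each
qualifying report contributes exactly once to the 2x2 table of its receipt
year.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "AdverseEventReport",
    "ContingencyTable2x2",
    "DrugEntry",
    "EmptyCohortError",
    "ReportParseError",
    "build_yearly_tables",
    "deduplicate",
    "load_reports",
    "read_tables_csv",
    "write_tables_csv",
]

#: Field map for the openFDA drug-event record subset.  Keys are logical
#: names; values are dotted paths into each JSON record.
DEFAULT_FIELD_MAP: Mapping[str, str] = {
    "report_id": "safetyreportid",
    "receipt_date": "receiptdate",
    "drugs": "patient.drug",
    "product_name": "medicinalproduct",
    "indication": "drugindication",
    "reactions": "patient.reaction",
    "reaction_term": "reactionmeddrapt",
}

_MANDATORY = ("report_id", "receipt_date", "drugs", "reactions")


class ReportParseError(ValueError):
    """A record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class EmptyCohortError(ValueError):
    """No report in the study window matched the cohort indication."""


@dataclass(frozen=True)
class DrugEntry:
    """One drug listed on a report, with its (optional) coded indication."""

    product_name: str
    indication: str | None = None


@dataclass(frozen=True)
class AdverseEventReport:
    """One spontaneous case report (the unit of observation)."""

    report_id: str
    receipt_year: int
    drugs: tuple[DrugEntry, ...]
    reactions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.drugs:
            raise ValueError("report must list at least one drug")
        if not self.reactions:
            raise ValueError("report must list at least one reaction")

    def has_drug(self, product_name: str) -> bool:
        term = product_name.upper()
        return any(d.product_name == term for d in self.drugs)

    def has_reaction(self, reaction_term: str) -> bool:
        term = reaction_term.upper()
        return term in self.reactions

    def has_indication(self, indication_term: str) -> bool:
        term = indication_term.upper()
        return any(d.indication == term for d in self.drugs)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Per-stratum exposed/unexposed x event/no-event counts.

    ``a`` exposed+event, ``b`` exposed only, ``c`` unexposed+event,
    ``d`` neither.
    """

    stratum: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {value!r}")
        if self.n == 0:
            raise ValueError("table has no reports (n = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _resolve(record: Mapping, dotted: str):
    current = record
    for part in dotted.split("."):
        if not isinstance(current, Mapping) or part not in current:
            return None
        current = current[part]
    return current


def _clean(term) -> str | None:
    if term is None:
        return None
    term = str(term).strip().upper()
    return term or None


def _iter_lines(source: Union[str, Path, IO[str], Iterable[str]]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def load_reports(
    source: Union[str, Path, IO[str], Iterable[str]],
    field_map: Mapping[str, str] | None = None,
) -> list[AdverseEventReport]:
    """Parse a JSON-Lines stream of adverse-event records.

    Parameters
    ----------
    source
        Path, open text handle, or iterable of lines; one JSON object per
        non-blank line.
    field_map
        Logical-name -> dotted-path mapping; defaults to the openFDA
        drug-event schema (:data:`DEFAULT_FIELD_MAP`).

    Returns
    -------
    list of AdverseEventReport
        Term strings upper-cased and whitespace-trimmed; the receipt year is
        the leading 4 digits of the receipt date.

    Raises
    ------
    ReportParseError
        On malformed JSON (carries the line number) or when a mandatory
        field (id, receipt date, drugs, reactions, product name, reaction
        term) is missing.
    """
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)

    reports: list[AdverseEventReport] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ReportParseError(
                f"line {lineno}: malformed record: {exc.msg}", line_number=lineno
            ) from exc
        if not isinstance(record, Mapping):
            raise ReportParseError(
                f"line {lineno}: record is not a JSON object", line_number=lineno
            )

        values = {}
        for name in _MANDATORY:
            value = _resolve(record, fmap[name])
            if value in (None, "", []):
                raise ReportParseError(
                    f"line {lineno}: missing mandatory field '{name}' ({fmap[name]})",
                    line_number=lineno,
                )
            values[name] = value

        date = str(values["receipt_date"]).strip()
        if len(date) < 4 or not date[:4].isdigit():
            raise ReportParseError(
                f"line {lineno}: receipt date {date!r} has no leading 4-digit year",
                line_number=lineno,
            )
        year = int(date[:4])

        drugs = []
        for entry in values["drugs"]:
            product = _clean(_resolve(entry, fmap["product_name"]))
            if product is None:
                raise ReportParseError(
                    f"line {lineno}: drug entry missing 'product_name' ({fmap['product_name']})",
                    line_number=lineno,
                )
            drugs.append(DrugEntry(product, _clean(_resolve(entry, fmap["indication"]))))

        reactions = []
        for entry in values["reactions"]:
            term = _clean(_resolve(entry, fmap["reaction_term"]))
            if term is None:
                raise ReportParseError(
                    f"line {lineno}: reaction entry missing 'reaction_term' "
                    f"({fmap['reaction_term']})",
                    line_number=lineno,
                )
            reactions.append(term)

        reports.append(
            AdverseEventReport(
                report_id=str(values["report_id"]).strip(),
                receipt_year=year,
                drugs=tuple(drugs),
                reactions=tuple(reactions),
            )
        )
    return reports


def deduplicate(reports: Sequence[AdverseEventReport]) -> list[AdverseEventReport]:
    """Collapse versioned case reports to one record per report id.

    Spontaneous-reporting systems store follow-up versions of the same case;
    a case must count once.  The record with the latest receipt year wins;
    on ties, the last occurrence in input order wins.
    """
    kept: dict[str, AdverseEventReport] = {}
    for report in reports:
        existing = kept.get(report.report_id)
        if existing is None or report.receipt_year >= existing.receipt_year:
            kept[report.report_id] = report
    return list(kept.values())


def _normalize_years(years) -> list[int]:
    if isinstance(years, range):
        return list(years)
    years = tuple(years)
    if len(years) == 2 and all(isinstance(y, int) for y in years) and years[1] >= years[0]:
        return list(range(years[0], years[1] + 1))
    return sorted(int(y) for y in years)


def build_yearly_tables(
    reports: Sequence[AdverseEventReport],
    drug_term: str,
    reaction_term: str,
    indication_term: str,
    years,
) -> list[ContingencyTable2x2]:
    """Reduce qualifying reports to one 2x2 table per receipt year.

    A report qualifies when its receipt year falls in ``years`` and any of
    its drugs carries ``indication_term``.  Exposure is exact
    (case-insensitive) product-name match against ``drug_term``; the event
    is exact match of any reaction against ``reaction_term``.  ``years`` is
    an inclusive ``(first, last)`` pair, a ``range``, or an explicit list.

    Raises
    ------
    EmptyCohortError
        When no report in the whole window qualifies.  Individual years with
        no qualifying reports are dropped with a logged warning.
    """
    for name, term in (
        ("drug_term", drug_term),
        ("reaction_term", reaction_term),
        ("indication_term", indication_term),
    ):
        if not term or not str(term).strip():
            raise ValueError(f"{name} must be non-empty")

    drug_term = drug_term.strip().upper()
    reaction_term = reaction_term.strip().upper()
    indication_term = indication_term.strip().upper()
    year_list = _normalize_years(years)
    year_set = set(year_list)

    counts = {year: [0, 0, 0, 0] for year in year_list}
    any_qualifying = False
    for report in reports:
        if report.receipt_year not in year_set:
            continue
        if not report.has_indication(indication_term):
            continue
        any_qualifying = True
        exposed = report.has_drug(drug_term)
        event = report.has_reaction(reaction_term)
        idx = (0 if event else 1) if exposed else (2 if event else 3)
        counts[report.receipt_year][idx] += 1

    if not any_qualifying:
        raise EmptyCohortError("empty cohort")

    tables = []
    for year in year_list:
        a, b, c, d = counts[year]
        if a + b + c + d == 0:
            logger.warning("year %d has no qualifying reports; dropped", year)
            continue
        tables.append(ContingencyTable2x2(str(year), a, b, c, d))
    return tables


def read_tables_csv(path: Union[str, Path]) -> list[ContingencyTable2x2]:
    """Read pre-tabulated per-stratum tables (columns stratum,a,b,c,d)."""
    tables = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        required = {"stratum", "a", "b", "c", "d"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"tables CSV must have columns {sorted(required)}")
        for row in reader:
            tables.append(
                ContingencyTable2x2(
                    row["stratum"], int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"])
                )
            )
    return tables


def write_tables_csv(tables: Sequence[ContingencyTable2x2], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["stratum", "a", "b", "c", "d"])
        for t in tables:
            writer.writerow([t.stratum, t.a, t.b, t.c, t.d])
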