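"""End-to-end orchestration of the disproportionality signal analysis.

Stages, in order: per-year tables -> per-year RORs -> heterogeneity ->
model selection -> pooled ROR -> whole-cohort chi-square and G tests ->
Egger regression -> leave-one-out sensitivity.  The assembled report is a
plain nested dict (JSON-serializable, byte-identical for identical inputs)
with internal consistency checks that fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import yaml

from .bias_diagnostics import LeaveOneOutResult, egger_test, funnel_data, leave_one_out
from .disproportionality import aggregate_tables, g_test, pearson_chi2, ror
from .meta_pool import (
    RANDOM_DL,
    heterogeneity,
    pool_fixed_mh,
    pool_random_dl,
    select_model,
)
from .report_store import (
    ContingencyTable2x2,
    build_yearly_tables,
    deduplicate,
    load_reports,
    read_tables_csv,
)

__all__ = ["PipelineStageError", "SignalReport", "StudyConfig", "run_signal_analysis", "write_report_files"]

_CONFIG_KEYS = {
    "cohort", "reports", "tables", "drug", "event", "indication",
    "year_start", "year_end", "alpha_model", "alpha_egger", "ci_level",
    "output_dir",
}


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class StudyConfig:
    """Cohort definition plus significance levels for one analysis run."""

    cohort: str
    drug: str
    event: str
    indication: str
    year_start: int
    year_end: int
    reports: str | None = None
    tables: str | None = None
    alpha_model: float = 0.05
    alpha_egger: float = 0.05
    ci_level: float = 0.95
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class SignalReport:
    """All stage outputs of one cohort analysis, JSON-serializable."""

    cohort: str
    tables: tuple[ContingencyTable2x2, ...]
    effects: tuple
    het: object
    model: str
    pooled: object
    cohort_chi2: object
    cohort_g: object
    egger: object
    loo: LeaveOneOutResult

    def validate(self, alpha_model: float = 0.05) -> None:
        if self.model != select_model(self.het, alpha_model):
            raise AssertionError("model tag inconsistent with the selection rule")
        k = len(self.tables)
        if any(e.result.k != k - 1 for e in self.loo.entries):
            raise AssertionError("leave-one-out entry has wrong stratum count")
        rors = [e.result.pooled_ror for e in self.loo.entries]
        if (self.loo.min_ror, self.loo.max_ror) != (min(rors), max(rors)):
            raise AssertionError("leave-one-out summary inconsistent with entries")
        if self.loo.min_ci_low > min(e.result.ci_low for e in self.loo.entries):
            raise AssertionError("leave-one-out min CI bound inconsistent")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "tables": [dataclasses.asdict(t) | {"n": t.n} for t in self.tables],
            "effects": [
                dataclasses.asdict(e) | {"se": e.se} for e in self.effects
            ],
            "heterogeneity": dataclasses.asdict(self.het),
            "model": self.model,
            "pooled": dataclasses.asdict(self.pooled),
            "cohort_tests": {
                "pearson_chi2": dataclasses.asdict(self.cohort_chi2),
                "g_test": dataclasses.asdict(self.cohort_g),
            },
            "egger": dataclasses.asdict(self.egger),
            "leave_one_out": {
                "entries": [
                    {
                        "omitted_stratum": e.omitted_stratum,
                        **dataclasses.asdict(e.result),
                    }
                    for e in self.loo.entries
                ],
                "min_ror": self.loo.min_ror,
                "max_ror": self.loo.max_ror,
                "min_ci_low": self.loo.min_ci_low,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        """Human-readable two-decimal summary (full precision lives in JSON)."""
        p = self.pooled
        lines = [
            f"cohort: {self.cohort}  ({len(self.tables)} strata)",
            f"heterogeneity: Q={self.het.Q:.2f} df={self.het.df} "
            f"p={self.het.p_value:.3g} I2={self.het.I2:.2f}% tau2={self.het.tau2:.4f}",
            f"model: {self.model}",
            f"pooled ROR: {p.pooled_ror:.2f} (95% CI {p.ci_low:.2f}-{p.ci_high:.2f}), "
            f"p={p.p_value:.3g}",
            f"cohort tests: chi2 p={self.cohort_chi2.p_value:.3g}, "
            f"G p={self.cohort_g.p_value:.3g}",
            f"Egger intercept: {self.egger.intercept:.3f} (p={self.egger.p_value:.3g})",
            f"leave-one-out ROR range: {self.loo.min_ror:.2f}-{self.loo.max_ror:.2f} "
            f"(lower CI bounds >= {self.loo.min_ci_low:.2f})",
        ]
        return "\n".join(lines)


def _stage(name: str):
    def decorator(fn):
        try:
            return fn()
        except Exception as exc:  # attach the stage name, keep the cause
            raise PipelineStageError(name, exc) from exc

    return decorator


def _resolve_tables(
    config: StudyConfig,
    tables: Sequence[ContingencyTable2x2] | None,
) -> list[ContingencyTable2x2]:
    if tables is not None:
        return list(tables)
    if config.tables is not None:
        return read_tables_csv(config.tables)
    if config.reports is not None:
        reports = deduplicate(load_reports(config.reports))
        return build_yearly_tables(
            reports, config.drug, config.event, config.indication,
            (config.year_start, config.year_end),
        )
    raise ValueError("config names neither a reports file nor a tables file")


def run_signal_analysis(
    config: StudyConfig,
    tables: Sequence[ContingencyTable2x2] | None = None,
) -> SignalReport:
    """Run every stage in order and return the assembled report.

    ``tables`` may be passed directly (e.g. simulator output); otherwise
    they are resolved from the config's ``tables`` CSV or ``reports``
    JSON-Lines file.  Stage failures propagate as
    :class:`PipelineStageError` naming the stage.
    """
    tabs = _stage("tables")(lambda: _resolve_tables(config, tables))
    effects = _stage("effects")(lambda: [ror(t, ci_level=config.ci_level) for t in tabs])
    het = _stage("heterogeneity")(lambda: heterogeneity(effects))
    model = _stage("model_selection")(lambda: select_model(het, config.alpha_model))

    def _pool():
        if model == RANDOM_DL:
            return pool_random_dl(effects, het, ci_level=config.ci_level)
        return pool_fixed_mh(tabs, ci_level=config.ci_level)

    pooled = _stage("pooling")(_pool)
    cohort_table = _stage("cohort_tests")(lambda: aggregate_tables(tabs, stratum="all"))
    chi2 = _stage("cohort_tests")(lambda: pearson_chi2(cohort_table))
    g = _stage("cohort_tests")(lambda: g_test(cohort_table))
    egger = _stage("egger")(lambda: egger_test(effects))
    loo = _stage("leave_one_out")(
        lambda: leave_one_out(tabs, model, ci_level=config.ci_level)
    )

    report = SignalReport(
        cohort=config.cohort,
        tables=tuple(tabs),
        effects=tuple(effects),
        het=het,
        model=model,
        pooled=pooled,
        cohort_chi2=chi2,
        cohort_g=g,
        egger=egger,
        loo=loo,
    )
    report.validate(config.alpha_model)
    return report


def write_report_files(report: SignalReport, outdir: Union[str, Path]) -> dict[str, Path]:
    """Serialize the report: report.json plus plot-ready TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["report"] = outdir / "report.json"
    paths["report"].write_text(report.to_json() + "\n", encoding="utf-8")

    effects_rows = [
        "stratum\ta\tb\tc\td\tror\tci_low\tci_high\tcorrected"
    ]
    for t, e in zip(report.tables, report.effects):
        effects_rows.append(
            f"{t.stratum}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
            f"{e.ror!r}\t{e.ci_low!r}\t{e.ci_high!r}\t{e.corrected}"
        )
    paths["effects"] = outdir / "effects.tsv"
    paths["effects"].write_text("\n".join(effects_rows) + "\n", encoding="utf-8")

    forest_rows = ["stratum\tror\tci_low\tci_high"]
    for e in report.effects:
        forest_rows.append(f"{e.stratum}\t{e.ror!r}\t{e.ci_low!r}\t{e.ci_high!r}")
    p = report.pooled
    forest_rows.append(f"pooled ({report.model})\t{p.pooled_ror!r}\t{p.ci_low!r}\t{p.ci_high!r}")
    paths["forest"] = outdir / "forest.tsv"
    paths["forest"].write_text("\n".join(forest_rows) + "\n", encoding="utf-8")

    paths["funnel"] = outdir / "funnel.tsv"
    funnel_data(report.effects).to_csv(paths["funnel"], sep="\t", index=False)

    loo_rows = ["omitted_year\tpooled_ror\tci_low\tci_high"]
    for entry in report.loo.entries:
        r = entry.result
        loo_rows.append(f"{entry.omitted_stratum}\t{r.pooled_ror!r}\t{r.ci_low!r}\t{r.ci_high!r}")
    loo_rows.append(f"min\t{report.loo.min_ror!r}\t{report.loo.min_ci_low!r}\t")
    loo_rows.append(f"max\t{report.loo.max_ror!r}\t\t")
    paths["loo"] = outdir / "loo.tsv"
    paths["loo"].write_text("\n".join(loo_rows) + "\n", encoding="utf-8")
    return paths
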