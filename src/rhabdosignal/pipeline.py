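"""End-to-end orchestration: clean -> disproportionality -> rule mining.

`run_pipeline` reads a dashboard-style CSV, cleans it, and writes per-statin
top-ADE tables, odds-ratio contrasts vs the reference statin (all reports
and monotherapy), male-vs-female contrasts, co-reported-ADE rules and DDI
candidate rules, plus a manifest recording the config hash, input checksum
and report counts at each filtering stage. Rendered tables round odds
ratios to 4 decimals and lifts to 2, and display p-values below 1e-4 as
"<0.0001"; full-precision columns are kept alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from rhabdosignal import arm, faers_io, signal_stats
from rhabdosignal.errors import ConfigError, RhabdosignalError

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of the FAERS-side analysis run."""

    input_reports: str
    output_dir: str
    statins: tuple[str, ...] = faers_io.STATINS
    reference_statin: str = "simvastatin"
    target_event: str = "rhabdomyolysis"
    synonym_map: str | None = None  # path; None -> shipped default
    min_cases: int = 5000
    lift_cutoff: float = 1.5
    top_k_ades: int = 10
    top_k_co_ades: int = 5
    top_k_ddi: int = 10
    min_rule_count: int = 10
    monotherapy: bool = True
    sex_stratified: bool = True

    def validate(self) -> None:
        if self.reference_statin not in self.statins:
            raise ConfigError("reference_statin must be in the statin list")
        if self.min_cases < 0 or self.lift_cutoff < 0:
            raise ConfigError("thresholds must be nonnegative")


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _or_row(statin: str, table, result) -> dict:
    return {
        "statin": statin,
        "with_ADE": table.a,
        "without_ADE": table.b,
        "odds_ratio": round(result.odds_ratio, 4),
        "ci_low": round(result.ci_low, 4),
        "ci_high": round(result.ci_high, 4),
        "p_value": result.p_value,
        "p_display": signal_stats.format_p(result.p_value),
        "is_signal": result.is_signal,
    }


def _rules_frame(rules: Sequence[arm.AssociationRule]) -> pd.DataFrame:
    records = arm.rules_to_records(rules)
    frame = pd.DataFrame(
        records,
        columns=["antecedent", "consequent", "count_xy", "support",
                 "confidence", "lift"],
    )
    if len(frame):
        frame["lift_display"] = frame["lift"].round(2)
    return frame


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full FAERS-side analysis; returns the manifest dict.

    On any stage failure, files already written for this run are removed
    and the error is re-raised with the stage name attached.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    stage = "setup"
    try:
        stage = "parse"
        synonyms = (
            faers_io.DrugSynonymMap.from_csv(config.synonym_map)
            if config.synonym_map else faers_io.DrugSynonymMap.default()
        )
        raw = faers_io.parse_reports(config.input_reports, synonyms=synonyms)
        logger.info("stage=parse in=%s out=%d", config.input_reports, len(raw))

        stage = "deduplicate"
        reports = faers_io.deduplicate(raw)
        logger.info("stage=deduplicate in=%d out=%d", len(raw), len(reports))

        stage = "drug_filter"
        eligible_all = faers_io.filter_drugs_by_case_count(reports, config.min_cases)
        statins = [s for s in config.statins if s in eligible_all]
        if config.reference_statin not in statins:
            raise ConfigError(
                f"reference statin {config.reference_statin!r} has fewer than "
                f"{config.min_cases} reports"
            )
        logger.info("stage=drug_filter in=%d statins out=%d", len(config.statins),
                    len(statins))

        stage = "top_ades"
        for statin in statins:
            ranked = signal_stats.top_k_events(reports, statin, config.top_k_ades)
            emit(pd.DataFrame(ranked, columns=["event", "count"]),
                 f"top_ades_{statin}.csv")

        stage = "disproportionality"
        rows = []
        counts = faers_io.drug_case_counts(reports)
        for statin in statins:
            table = signal_stats.build_contingency(
                reports, statin, config.reference_statin, config.target_event
            )
            result = signal_stats.odds_ratio(table)
            rows.append(_or_row(statin, table, result))
        emit(pd.DataFrame(rows), "or_all_reports.csv")

        mono_counts: dict[str, int] = {}
        if config.monotherapy:
            stage = "monotherapy"
            mono_reports = [
                r for s in statins for r in faers_io.select_monotherapy(reports, s)
            ]
            mono_counts = {s: sum(1 for r in mono_reports if s in r.drugs)
                           for s in statins}
            rows = []
            for statin in statins:
                table = signal_stats.build_contingency(
                    mono_reports, statin, config.reference_statin, config.target_event
                )
                rows.append(_or_row(statin, table, signal_stats.odds_ratio(table)))
            emit(pd.DataFrame(rows), "or_monotherapy.csv")

        if config.sex_stratified:
            stage = "sex_stratified"
            rows = []
            for statin in statins:
                table = signal_stats.sex_stratified_table(
                    reports, statin, config.target_event
                )
                result = signal_stats.odds_ratio(table)
                rows.append(
                    {
                        "statin": statin,
                        "male_with_ADE": table.a,
                        "male_without_ADE": table.b,
                        "female_with_ADE": table.c,
                        "female_without_ADE": table.d,
                        "odds_ratio": round(result.odds_ratio, 4),
                        "ci_low": round(result.ci_low, 4),
                        "ci_high": round(result.ci_high, 4),
                        "p_value": result.p_value,
                        "p_display": signal_stats.format_p(result.p_value),
                        "is_signal": result.is_signal,
                    }
                )
            emit(pd.DataFrame(rows), "or_sex.csv")

        stage = "co_reported_ades"
        for statin in statins:
            rules = arm.co_reported_ades(
                reports, statin, config.target_event,
                lift_cutoff=config.lift_cutoff, k=config.top_k_co_ades,
                min_count=config.min_rule_count,
            )
            emit(_rules_frame(rules), f"co_ades_{statin}.csv")

        stage = "ddi_rules"
        for statin in statins:
            rules = arm.ddi_rules(
                reports, statin, config.target_event,
                lift_cutoff=config.lift_cutoff, k=config.top_k_ddi,
                min_count=config.min_rule_count,
            )
            emit(_rules_frame(rules), f"ddi_{statin}.csv")

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": _config_hash(config),
            "input_checksum": _file_checksum(config.input_reports),
            "stage_counts": {
                "raw_rows": len(raw),
                "after_dedup": len(reports),
                "statin_case_counts": {s: counts.get(s, 0) for s in statins},
                "monotherapy_counts": mono_counts,
            },
            "eligible_statins": statins,
            "outputs": sorted(p.name for p in written),
        }
        path = outdir / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(path)
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RhabdosignalError(f"[stage={stage}] {exc}") from exc


__all__ = ["AnalysisConfig", "run_pipeline"]
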