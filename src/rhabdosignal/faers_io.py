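"""Reading, normalising and filtering FAERS-dashboard-style report tables.

The public FAERS dashboard exports one CSV row per case with multi-valued
cells (suspect products, active ingredients, reactions) joined by ";".
This module parses that dialect into :class:`AdverseEventReport` records,
maps brand names onto canonical generic drug names, removes
literature-derived and duplicate-case reports, and applies the cohort
inclusion rules (minimum case volume, monotherapy restriction).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from datetime import date, datetime
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from rhabdosignal.errors import SchemaError

logger = logging.getLogger(__name__)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


_SEX_ALIASES = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
}


def normalize_sex(raw: str | None) -> Sex:
    """Map free-text sex strings onto the three-level enum.

    "M"/"Male" and "F"/"Female" (any case) are recognised; everything else,
    including blanks, is :attr:`Sex.UNKNOWN`. Unknown-sex reports are kept
    everywhere except sex-stratified contrasts.
    """
    if raw is None:
        return Sex.UNKNOWN
    return _SEX_ALIASES.get(raw.strip().lower(), Sex.UNKNOWN)


def normalize_term(term: str) -> str:
    """Canonicalise a MedDRA preferred term: trim, collapse spaces, lowercase."""
    return re.sub(r"\s+", " ", term.strip()).lower()


@dataclass(frozen=True)
class AdverseEventReport:
    """One spontaneous adverse-event report.

    ``drugs`` holds canonical lowercase generic names after synonym mapping;
    ``ades`` holds case-normalised MedDRA preferred terms. Dosage is absent
    from dashboard exports and is not modelled.
    """

    case_id: str
    drugs: frozenset[str]
    ades: frozenset[str]
    sex: Sex = Sex.UNKNOWN
    age_years: float | None = None
    from_literature: bool = False
    received_date: date | None = None
    raw_suspect_products: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be nonempty")


class DrugSynonymMap:
    """Case-insensitive brand/variant -> canonical generic name lookup.

    Canonical names map to themselves; unknown names are returned lowercased
    so that downstream set operations stay case-stable.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for variant, canonical in (mapping or {}).items():
            self.add(variant, canonical)

    def add(self, variant: str, canonical: str) -> None:
        canonical = canonical.strip().lower()
        self._map[variant.strip().lower()] = canonical
        self._map.setdefault(canonical, canonical)

    def canonical(self, name: str) -> str:
        key = name.strip().lower()
        return self._map.get(key, key)

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._map

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugSynonymMap":
        """Load a two-column (variant, canonical) CSV."""
        m = cls()
        with open(path, newline="", encoding="utf-8-sig") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "variant" not in reader.fieldnames:
                raise SchemaError("variant", str(path))
            if "canonical" not in reader.fieldnames:
                raise SchemaError("canonical", str(path))
            for row in reader:
                m.add(row["variant"], row["canonical"])
        return m

    @classmethod
    def default(cls) -> "DrugSynonymMap":
        """The shipped map covering the five statins and their brand names."""
        ref = resources.files("rhabdosignal.datasets") / "statin_synonyms.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


STATINS = ("atorvastatin", "simvastatin", "lovastatin", "rosuvastatin", "pravastatin")


@dataclass
class FaersDialect:
    """Column names and separators of a dashboard-style export.

    Defaults follow the public-dashboard CSV headers; all are configurable
    because exports vary across dashboard versions.
    """

    case_id: str = "Case ID"
    suspect_products: str = "Suspect Product Names"
    active_ingredients: str = "Suspect Product Active Ingredients"
    reactions: str = "Reactions"
    sex: str = "Sex"
    age: str = "Patient Age"
    source: str = "Report Source"
    received_date: str = "Initial FDA Received Date"
    delimiter: str = ","
    list_separator: str = ";"
    # a report counts as literature-derived when its source matches any pattern
    literature_patterns: tuple[str, ...] = ("literature",)

    mandatory = ("case_id", "suspect_products", "reactions", "sex", "source")

    def is_literature(self, source_value: str) -> bool:
        value = source_value.lower()
        return any(pat.lower() in value for pat in self.literature_patterns)


def _split_cell(cell: str, sep: str) -> list[str]:
    return [part.strip() for part in cell.split(sep) if part.strip()]


def _parse_date(raw: str) -> date | None:
    raw = raw.strip()
    if not raw:
        return None
    for fmt in ("%Y-%m-%d", "%m/%d/%Y", "%d-%b-%Y"):
        try:
            return datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    return None


def parse_reports(
    path: str | Path,
    dialect: FaersDialect | None = None,
    synonyms: DrugSynonymMap | None = None,
) -> list[AdverseEventReport]:
    """Parse a dashboard-style CSV into report records.

    Drug names from both the suspect-product and active-ingredient columns
    are unioned and passed through the synonym map; unknown products are
    kept verbatim (lowercased). Raises :class:`SchemaError` if a mandatory
    column is absent; an empty file yields an empty list with a warning.
    """
    dialect = dialect or FaersDialect()
    synonyms = synonyms if synonyms is not None else DrugSynonymMap.default()

    frame = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, keep_default_na=False,
        encoding="utf-8-sig",
    )
    for attr in dialect.mandatory:
        column = getattr(dialect, attr)
        if column not in frame.columns:
            raise SchemaError(column, str(path))
    if frame.empty:
        logger.warning("no report rows in %s", path)
        return []

    has_ingredients = dialect.active_ingredients in frame.columns
    has_age = dialect.age in frame.columns
    has_date = dialect.received_date in frame.columns

    reports: list[AdverseEventReport] = []
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        raw_products = _split_cell(row[dialect.suspect_products], dialect.list_separator)
        names = list(raw_products)
        if has_ingredients:
            names += _split_cell(row[dialect.active_ingredients], dialect.list_separator)
        drugs = frozenset(synonyms.canonical(n) for n in names)
        ades = frozenset(
            normalize_term(t)
            for t in _split_cell(row[dialect.reactions], dialect.list_separator)
        )
        age: float | None = None
        if has_age and row[dialect.age].strip():
            try:
                age = float(row[dialect.age])
            except ValueError:
                age = None
        reports.append(
            AdverseEventReport(
                case_id=row[dialect.case_id].strip(),
                drugs=drugs,
                ades=ades,
                sex=normalize_sex(row[dialect.sex]),
                age_years=age,
                from_literature=dialect.is_literature(row[dialect.source]),
                received_date=_parse_date(row[dialect.received_date]) if has_date else None,
                raw_suspect_products=tuple(raw_products),
            )
        )
    return reports


CANONICAL_COLUMNS = (
    "case_id", "drugs", "ades", "sex", "age_years", "from_literature", "received_date",
)


def write_reports_csv(reports: Iterable[AdverseEventReport], path: str | Path) -> None:
    """Serialise reports to the canonical fixed-column CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    r.case_id,
                    ";".join(sorted(r.drugs)),
                    ";".join(sorted(r.ades)),
                    r.sex.value,
                    "" if r.age_years is None else r.age_years,
                    str(r.from_literature).lower(),
                    "" if r.received_date is None else r.received_date.isoformat(),
                ]
            )


def read_reports_csv(path: str | Path) -> list[AdverseEventReport]:
    """Read the canonical CSV written by :func:`write_reports_csv`."""
    reports = []
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        for col in CANONICAL_COLUMNS:
            if reader.fieldnames is None or col not in reader.fieldnames:
                raise SchemaError(col, str(path))
        for row in reader:
            reports.append(
                AdverseEventReport(
                    case_id=row["case_id"],
                    drugs=frozenset(d for d in row["drugs"].split(";") if d),
                    ades=frozenset(a for a in row["ades"].split(";") if a),
                    sex=Sex(row["sex"]),
                    age_years=float(row["age_years"]) if row["age_years"] else None,
                    from_literature=row["from_literature"] == "true",
                    received_date=_parse_date(row["received_date"]),
                )
            )
    return reports


def deduplicate(reports: Sequence[AdverseEventReport]) -> list[AdverseEventReport]:
    """Drop literature-derived reports, then collapse duplicate case IDs.

    Among reports sharing a case ID the one with the latest received date
    survives; when dates tie or are missing the row appearing last in input
    order wins. Output order follows the first appearance of each surviving
    case ID, so the operation is deterministic and idempotent.
    """
    best: dict[str, tuple[int, AdverseEventReport]] = {}
    first_seen: dict[str, int] = {}
    for idx, report in enumerate(reports):
        if report.from_literature:
            continue
        cid = report.case_id
        first_seen.setdefault(cid, idx)
        if cid not in best:
            best[cid] = (idx, report)
            continue
        _, incumbent = best[cid]
        new_key = (report.received_date or date.min, idx)
        old_key = (incumbent.received_date or date.min, best[cid][0])
        if new_key >= old_key:
            best[cid] = (idx, report)
    ordered = sorted(best, key=first_seen.__getitem__)
    return [best[cid][1] for cid in ordered]


def drug_case_counts(reports: Sequence[AdverseEventReport]) -> dict[str, int]:
    """Number of reports naming each drug (a report counts once per drug)."""
    counts: dict[str, int] = {}
    for report in reports:
        for drug in report.drugs:
            counts[drug] = counts.get(drug, 0) + 1
    return counts


def filter_drugs_by_case_count(
    reports: Sequence[AdverseEventReport], min_cases: int = 5000
) -> set[str]:
    """Drugs whose post-dedup report count strictly exceeds ``min_cases``."""
    if min_cases < 0:
        raise ValueError("min_cases must be nonnegative")
    return {d for d, n in drug_case_counts(reports).items() if n > min_cases}


def select_monotherapy(
    reports: Sequence[AdverseEventReport], drug: str
) -> list[AdverseEventReport]:
    """Reports whose drug set is exactly ``{drug}`` (no co-medication)."""
    target = frozenset({drug})
    return [r for r in reports if r.drugs == target]


__all__ = [
    "AdverseEventReport",
    "DrugSynonymMap",
    "FaersDialect",
    "Sex",
    "STATINS",
    "CANONICAL_COLUMNS",
    "normalize_sex",
    "normalize_term",
    "parse_reports",
    "read_reports_csv",
    "write_reports_csv",
    "deduplicate",
    "drug_case_counts",
    "filter_drugs_by_case_count",
    "select_monotherapy",
]
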