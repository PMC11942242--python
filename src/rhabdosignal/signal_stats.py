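"""Disproportionality statistics on 2x2 exposure-by-event tables.

The reporting odds ratio (ROR) compares the odds of an adverse event being
reported under an exposure drug against a reference drug:

    OR = (a*d) / (b*c)

with Woolf's log-normal interval, ``SE[ln OR] = sqrt(1/a + 1/b + 1/c + 1/d)``
and ``CI = exp(ln OR +/- 1.96 SE)``. A safety signal is declared when the
lower 95% bound exceeds 1.0. The same machinery drives the drug-vs-reference
contrasts, the male-vs-female contrasts, and optional age-band strata.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from rhabdosignal.errors import EmptyGroupError, UndefinedEstimateError
from rhabdosignal.faers_io import AdverseEventReport, Sex, normalize_term

Z_95 = 1.96  # normal quantile used by the Medcalc convention


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of (exposure, reference) x (event, no event) reports.

    ``a``/``b`` are exposure-group reports with/without the event,
    ``c``/``d`` the reference group likewise.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("contingency cells must be nonnegative integers")

    @property
    def exposure_total(self) -> int:
        return self.a + self.b

    @property
    def reference_total(self) -> int:
        return self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """Exchange exposure and reference groups (maps OR to 1/OR)."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    is_signal: bool
    correction_applied: bool = False


def odds_ratio(
    table: ContingencyTable2x2, zero_cell_correction: bool = True
) -> OddsRatioResult:
    """Woolf odds ratio with 95% CI, two-sided normal p, and signal flag.

    A zero cell makes the estimate undefined; with ``zero_cell_correction``
    the Haldane--Anscombe +0.5 is added to all four cells (flagged in the
    result), otherwise :class:`UndefinedEstimateError` is raised.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = False
    if min(a, b, c, d) == 0.0:
        if not zero_cell_correction:
            raise UndefinedEstimateError(
                f"zero cell in table (a={table.a}, b={table.b}, c={table.c}, d={table.d})"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - Z_95 * se)
    ci_high = math.exp(log_or + Z_95 * se)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        is_signal=ci_low > 1.0,
        correction_applied=corrected,
    )


def build_contingency(
    reports: Sequence[AdverseEventReport],
    exposure_drug: str,
    reference_drug: str,
    event_term: str,
) -> ContingencyTable2x2:
    """Per-drug-marginal 2x2 for exposure vs reference drug.

    A report naming both drugs contributes to both groups; this matches
    per-drug dashboard totals, from which the published tables are
    reproducible without cross-exclusion.
    """
    event = normalize_term(event_term)
    a = b = c = d = 0
    for report in reports:
        has_event = event in report.ades
        if exposure_drug in report.drugs:
            a += has_event
            b += not has_event
        if reference_drug in report.drugs:
            c += has_event
            d += not has_event
    if a + b == 0:
        raise EmptyGroupError(f"no reports name exposure drug {exposure_drug!r}")
    if c + d == 0:
        raise EmptyGroupError(f"no reports name reference drug {reference_drug!r}")
    return ContingencyTable2x2(a, b, c, d)


def sex_stratified_or(
    reports: Sequence[AdverseEventReport],
    drug: str,
    event_term: str,
    zero_cell_correction: bool = True,
) -> OddsRatioResult:
    """Male-vs-female reporting odds of ``event_term`` among ``drug`` reports.

    Unknown-sex reports are excluded here (and only here). Raises
    :class:`EmptyGroupError` when either sex stratum is empty.
    """
    event = normalize_term(event_term)
    a = b = c = d = 0
    for report in reports:
        if drug not in report.drugs or report.sex is Sex.UNKNOWN:
            continue
        has_event = event in report.ades
        if report.sex is Sex.MALE:
            a += has_event
            b += not has_event
        else:
            c += has_event
            d += not has_event
    if a + b == 0:
        raise EmptyGroupError(f"no male reports for drug {drug!r}")
    if c + d == 0:
        raise EmptyGroupError(f"no female reports for drug {drug!r}")
    return odds_ratio(ContingencyTable2x2(a, b, c, d), zero_cell_correction)


def sex_stratified_table(
    reports: Sequence[AdverseEventReport], drug: str, event_term: str
) -> ContingencyTable2x2:
    """The male-vs-female 2x2 underlying :func:`sex_stratified_or`."""
    event = normalize_term(event_term)
    a = b = c = d = 0
    for report in reports:
        if drug not in report.drugs or report.sex is Sex.UNKNOWN:
            continue
        has_event = event in report.ades
        if report.sex is Sex.MALE:
            a += has_event
            b += not has_event
        else:
            c += has_event
            d += not has_event
    return ContingencyTable2x2(a, b, c, d)


def age_stratified_or(
    reports: Sequence[AdverseEventReport],
    drug: str,
    event_term: str,
    reference_drug: str,
    bands: Sequence[tuple[float, float]],
) -> dict[tuple[float, float], OddsRatioResult]:
    """Drug-vs-reference OR within user-supplied [low, high) age bands.

    No default bands are defined; reports with missing age are skipped.
    """
    out: dict[tuple[float, float], OddsRatioResult] = {}
    for low, high in bands:
        subset = [
            r for r in reports
            if r.age_years is not None and low <= r.age_years < high
        ]
        table = build_contingency(subset, drug, reference_drug, event_term)
        out[(low, high)] = odds_ratio(table)
    return out


def top_k_events(
    reports: Sequence[AdverseEventReport], drug: str, k: int = 10
) -> list[tuple[str, int]]:
    """The ``k`` most frequently reported ADE terms among ``drug`` reports.

    Ranked by descending count, ties broken alphabetically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for report in reports:
        if drug in report.drugs:
            counts.update(report.ades)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def format_p(p: float, floor: float = 1e-4) -> str:
    """Render a p-value the way the published tables do (``<0.0001`` floor)."""
    return f"<{floor:g}" if p < floor else f"{p:.4g}"


__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "Z_95",
    "odds_ratio",
    "build_contingency",
    "sex_stratified_or",
    "sex_stratified_table",
    "age_stratified_or",
    "top_k_events",
    "format_p",
]
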