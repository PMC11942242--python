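"""Synthetic FAERS-like cohorts and expression matrices with planted truth.

The cohort generator emulates the dashboard-export schema end to end: each
report carries one statin (drawn with report-volume weights), independent
co-medications, sex, age, a target adverse event whose probability follows
a logistic model (statin shift + male shift + drug--drug-interaction
terms), a vocabulary of background ADEs, and planted co-reporting
dependence for chosen ADE pairs. Literature flags and duplicate case IDs
are injected so the cleaning stage has something to remove. Every planted
parameter and every realized count is recorded in a truth object, making
each pipeline stage testable without any external download.

Defaults mirror the published study conditions: the five statins at their
reported report volumes, a reference (simvastatin) rhabdomyolysis
reporting rate near 0.10, statin log-odds shifts equal to the published
odds ratios, a twofold male excess, and lift-style co-reporting for acute
kidney injury.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from rhabdosignal.errors import ConfigError
from rhabdosignal.faers_io import AdverseEventReport, FaersDialect, Sex

BRAND_NAMES = {
    "atorvastatin": "Lipitor",
    "simvastatin": "Zocor",
    "lovastatin": "Mevacor",
    "rosuvastatin": "Crestor",
    "pravastatin": "Pravachol",
}

# report volumes as published for the five statins, normalised to weights
_STATIN_VOLUMES = {
    "simvastatin": 51446,
    "atorvastatin": 101774,
    "rosuvastatin": 55489,
    "lovastatin": 15701,
    "pravastatin": 12880,
}

# published odds ratios vs simvastatin, planted as log-odds shifts
_STATIN_OR = {
    "simvastatin": 1.0,
    "rosuvastatin": 0.3840,
    "atorvastatin": 0.3098,
    "pravastatin": 0.2178,
    "lovastatin": 0.1798,
}


@dataclass(frozen=True)
class CoAdeSpec:
    """Plant pairwise lift between the target event and a background ADE.

    ``within_drug`` restricts the dependence (and the lift guarantee) to
    reports naming that statin; None plants it cohort-wide.
    """

    partner: str
    target_lift: float
    within_drug: str | None = None


@dataclass(frozen=True)
class DdiSpec:
    """Multiply the target-event odds by ``odds_factor`` under co-exposure."""

    statin: str
    comedication: str
    odds_factor: float


def _default_statins() -> dict[str, float]:
    total = sum(_STATIN_VOLUMES.values())
    return {k: v / total for k, v in _STATIN_VOLUMES.items()}


def _default_shifts() -> dict[str, float]:
    return {k: math.log(v) for k, v in _STATIN_OR.items()}


def _default_background() -> dict[str, float]:
    return {
        "myalgia": 0.15,
        "drug interaction": 0.06,
        "fatigue": 0.06,
        "arthralgia": 0.06,
        "blood creatine phosphokinase increased": 0.05,
        "muscular weakness": 0.05,
        "asthenia": 0.05,
        "pain in extremity": 0.05,
        "nausea": 0.04,
        "dizziness": 0.04,
        "headache": 0.04,
        "fall": 0.03,
        "myopathy": 0.02,
        "acute kidney injury": 0.02,
    }


def _default_comeds() -> dict[str, float]:
    return {
        "acetaminophen": 0.06,
        "furosemide": 0.05,
        "metoprolol": 0.05,
        "pantoprazole": 0.05,
        "clopidogrel": 0.04,
        "lisinopril": 0.04,
        "omeprazole": 0.04,
        "levothyroxine": 0.04,
        "allopurinol": 0.03,
        "nitroglycerin": 0.02,
    }


@dataclass
class CohortConfig:
    """Planted structure of a synthetic report cohort (see module docstring)."""

    n_reports: int = 50_000
    statins: dict[str, float] = field(default_factory=_default_statins)
    statin_event_logodds: dict[str, float] = field(default_factory=_default_shifts)
    baseline_event_logit: float = math.log(0.10 / 0.90)
    target_event: str = "rhabdomyolysis"
    sex_probs: tuple[float, float, float] = (0.48, 0.47, 0.05)  # male, female, unknown
    male_event_logodds: float = math.log(2.0)
    background_ades: dict[str, float] = field(default_factory=_default_background)
    comedications: dict[str, float] = field(default_factory=_default_comeds)
    co_ade: tuple[CoAdeSpec, ...] = (
        CoAdeSpec("acute kidney injury", 6.0, within_drug="simvastatin"),
    )
    ddi: tuple[DdiSpec, ...] = (
        DdiSpec("simvastatin", "furosemide", 3.0),
        DdiSpec("rosuvastatin", "pantoprazole", 3.0),
    )
    brand_name_rate: float = 0.3
    duplicate_rate: float = 0.05
    literature_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be positive")
        for name, p in {**self.statins, **self.comedications,
                        **self.background_ades}.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability for {name!r} outside [0, 1]")
        for rate in (self.brand_name_rate, self.duplicate_rate, self.literature_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError("rates must lie in [0, 1]")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ConfigError("sex_probs must sum to 1")
        if abs(sum(self.statins.values()) - 1.0) > 1e-9:
            raise ConfigError("statin weights must sum to 1")
        for spec in self.co_ade:
            if spec.target_lift <= 0:
                raise ConfigError(f"lift target for {spec.partner!r} must be > 0")
            if spec.partner not in self.background_ades:
                raise ConfigError(f"co-ADE partner {spec.partner!r} not in vocabulary")


@dataclass
class CohortTruth:
    """Planted parameters plus realized counts of the deduplicated cohort."""

    n_rows_emitted: int
    n_unique_nonliterature: int
    n_literature: int
    n_duplicate_rows: int
    statin_counts: dict[str, int]
    # per statin: [with event, without event], all reports then monotherapy
    contingency: dict[str, tuple[int, int]]
    monotherapy: dict[str, tuple[int, int]]
    # per statin: male (with, without), female (with, without)
    sex_cells: dict[str, tuple[int, int, int, int]]
    co_ade_lift: dict[str, float]
    ddi_lift: dict[str, float]
    planted: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[AdverseEventReport], CohortTruth]:
    """Sample a cohort per the config; returns (reports, truth record).

    The emitted list includes literature-flagged rows and duplicate
    case-ID rows; the truth record's counts describe the cohort after
    cleaning (literature removal + case-ID collapsing), which is what the
    pipeline analyses.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    statin_names = list(config.statins)
    statin_idx = rng.choice(len(statin_names), size=n, p=list(config.statins.values()))
    statin = np.array(statin_names, dtype=object)[statin_idx]

    comed_names = list(config.comedications)
    comed = (
        rng.random((n, len(comed_names))) < np.array(list(config.comedications.values()))
        if comed_names else np.zeros((n, 0), dtype=bool)
    )

    sex_draw = rng.choice(3, size=n, p=list(config.sex_probs))
    sex = np.array([Sex.MALE, Sex.FEMALE, Sex.UNKNOWN], dtype=object)[sex_draw]

    logit = np.full(n, config.baseline_event_logit)
    for name, shift in config.statin_event_logodds.items():
        logit[statin == name] += shift
    logit[sex_draw == 0] += config.male_event_logodds
    for spec in config.ddi:
        if spec.comedication in comed_names:
            j = comed_names.index(spec.comedication)
            logit[(statin == spec.statin) & comed[:, j]] += math.log(spec.odds_factor)
    p_event = 1.0 / (1.0 + np.exp(-logit))
    target = rng.random(n) < p_event

    # background ADEs: independent draws, except planted co-reporting partners
    partners = {spec.partner: spec for spec in config.co_ade}
    ade_names = list(config.background_ades)
    ade_matrix = np.zeros((n, len(ade_names)), dtype=bool)
    for j, (term, q) in enumerate(config.background_ades.items()):
        if term not in partners:
            ade_matrix[:, j] = rng.random(n) < q
            continue
        spec = partners[term]
        mask = (statin == spec.within_drug) if spec.within_drug else np.ones(n, bool)
        if not mask.any():
            raise ConfigError(f"empty conditioning subset for co-ADE {term!r}")
        p_bar = float(target[mask].mean())
        lift = spec.target_lift
        c1 = lift * q
        if p_bar >= 1.0 or c1 > 1.0 or lift * p_bar > 1.0:
            raise ConfigError(
                f"infeasible lift target {lift} for pair "
                f"({config.target_event!r}, {term!r})"
            )
        c0 = q * (1.0 - lift * p_bar) / (1.0 - p_bar)
        prob = np.where(mask, np.where(target, c1, c0), q)
        ade_matrix[:, j] = rng.random(n) < prob

    age = np.clip(np.round(rng.normal(62.0, 12.0, size=n)), 18, 95)
    age_missing = rng.random(n) < 0.10
    start = date(2015, 1, 1)
    day_offsets = rng.integers(0, 3650, size=n)
    literature = rng.random(n) < config.literature_rate
    use_brand = rng.random(n) < config.brand_name_rate

    target_term = config.target_event
    reports: list[AdverseEventReport] = []
    for i in range(n):
        drugs = {statin[i]} | {comed_names[j] for j in np.nonzero(comed[i])[0]}
        ades = {ade_names[j] for j in np.nonzero(ade_matrix[i])[0]}
        if target[i]:
            ades.add(target_term)
        display_statin = (
            BRAND_NAMES.get(statin[i], statin[i]) if use_brand[i] else statin[i]
        )
        raw = (display_statin,) + tuple(
            comed_names[j] for j in np.nonzero(comed[i])[0]
        )
        reports.append(
            AdverseEventReport(
                case_id=f"C{i:07d}",
                drugs=frozenset(drugs),
                ades=frozenset(ades),
                sex=sex[i],
                age_years=None if age_missing[i] else float(age[i]),
                from_literature=bool(literature[i]),
                received_date=start + timedelta(days=int(day_offsets[i])),
                raw_suspect_products=raw,
            )
        )

    # duplicate rows: copies of non-literature reports with an earlier date
    nonlit_idx = np.nonzero(~literature)[0]
    n_dup = int(math.floor(config.duplicate_rate * n))
    dup_idx = rng.choice(nonlit_idx, size=min(n_dup, nonlit_idx.size), replace=False)
    duplicates = []
    for i in dup_idx:
        orig = reports[i]
        duplicates.append(
            AdverseEventReport(
                case_id=orig.case_id,
                drugs=orig.drugs,
                ades=orig.ades,
                sex=orig.sex,
                age_years=orig.age_years,
                from_literature=False,
                received_date=(orig.received_date or start) - timedelta(days=30),
                raw_suspect_products=orig.raw_suspect_products,
            )
        )
    emitted = reports + duplicates

    truth = _tally_truth(config, statin, comed, comed_names, sex_draw, target,
                         ade_matrix, ade_names, literature, len(duplicates))
    return emitted, truth


def _tally_truth(config, statin, comed, comed_names, sex_draw, target,
                 ade_matrix, ade_names, literature, n_dup) -> CohortTruth:
    keep = ~literature
    statin_counts: dict[str, int] = {}
    contingency: dict[str, tuple[int, int]] = {}
    monotherapy: dict[str, tuple[int, int]] = {}
    sex_cells: dict[str, tuple[int, int, int, int]] = {}
    mono_mask = ~comed.any(axis=1)
    for name in config.statins:
        m = keep & (statin == name)
        statin_counts[name] = int(m.sum())
        contingency[name] = (int((m & target).sum()), int((m & ~target).sum()))
        mm = m & mono_mask
        monotherapy[name] = (int((mm & target).sum()), int((mm & ~target).sum()))
        male, female = m & (sex_draw == 0), m & (sex_draw == 1)
        sex_cells[name] = (
            int((male & target).sum()), int((male & ~target).sum()),
            int((female & target).sum()), int((female & ~target).sum()),
        )

    co_ade_lift: dict[str, float] = {}
    for spec in config.co_ade:
        mask = keep & ((statin == spec.within_drug) if spec.within_drug
                       else np.ones_like(keep))
        j = ade_names.index(spec.partner)
        n_sub = int(mask.sum())
        n_t, n_e = int(target[mask].sum()), int(ade_matrix[mask, j].sum())
        n_te = int((target & ade_matrix[:, j] & mask).sum())
        if n_t and n_e:
            co_ade_lift[spec.partner] = (n_te / n_sub) / ((n_t / n_sub) * (n_e / n_sub))

    ddi_lift: dict[str, float] = {}
    for spec in config.ddi:
        if spec.comedication not in comed_names:
            continue
        j = comed_names.index(spec.comedication)
        mask = keep & (statin == spec.statin)
        n_sub = int(mask.sum())
        n_g, n_t = int(comed[mask, j].sum()), int(target[mask].sum())
        n_gt = int((comed[:, j] & target & mask).sum())
        if n_g and n_t:
            key = f"{spec.statin}+{spec.comedication}"
            ddi_lift[key] = (n_gt / n_sub) / ((n_g / n_sub) * (n_t / n_sub))

    planted = {
        "statin_event_logodds": dict(config.statin_event_logodds),
        "baseline_event_logit": config.baseline_event_logit,
        "male_event_logodds": config.male_event_logodds,
        "co_ade": [asdict(s) for s in config.co_ade],
        "ddi": [asdict(s) for s in config.ddi],
        "seed": config.seed,
    }
    return CohortTruth(
        n_rows_emitted=int(len(statin) + n_dup),
        n_unique_nonliterature=int(keep.sum()),
        n_literature=int(literature.sum()),
        n_duplicate_rows=n_dup,
        statin_counts=statin_counts,
        contingency=contingency,
        monotherapy=monotherapy,
        sex_cells=sex_cells,
        co_ade_lift=co_ade_lift,
        ddi_lift=ddi_lift,
        planted=planted,
    )


def write_faers_csv(
    reports: Sequence[AdverseEventReport],
    path: str | Path,
    dialect: FaersDialect | None = None,
) -> None:
    """Emit reports in the dashboard-export dialect consumed by the parser.

    The suspect-products column carries the display names (brand or
    generic) while the active-ingredients column always carries canonical
    generics, mirroring real exports where either column may name a drug.
    """
    dialect = dialect or FaersDialect()
    sep = dialect.list_separator + " "
    header = [
        dialect.case_id, dialect.suspect_products, dialect.active_ingredients,
        dialect.reactions, dialect.sex, dialect.age, dialect.source,
        dialect.received_date,
    ]
    sex_out = {Sex.MALE: "Male", Sex.FEMALE: "Female", Sex.UNKNOWN: "Not Specified"}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        import csv

        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(header)
        for r in reports:
            writer.writerow(
                [
                    r.case_id,
                    sep.join(r.raw_suspect_products or sorted(r.drugs)),
                    sep.join(sorted(r.drugs)),
                    sep.join(sorted(r.ades)),
                    sex_out[r.sex],
                    "" if r.age_years is None else int(r.age_years),
                    "Literature" if r.from_literature else "Health Professional",
                    "" if r.received_date is None else r.received_date.isoformat(),
                ]
            )


@dataclass
class ExpressionConfig:
    """Planted structure of a synthetic two-group expression matrix.

    Defaults follow the study's assay design: 4 replicates per arm, with
    2000 genes, 100 planted differentially expressed at |log2 FC| = 2 and
    residual standard deviation 0.5.
    """

    n_genes: int = 2000
    n_de: int = 100
    log_fc_effect: float = 2.0
    residual_sd: float = 0.5
    n_replicates: int = 4
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_de > self.n_genes:
            raise ConfigError("n_de cannot exceed n_genes")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates per group")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be positive")


def generate_expression(config: ExpressionConfig):
    """Gaussian log2-scale matrix with planted mean shifts; returns (matrix, truth).

    Truth maps each planted gene symbol to "up" or "down" (balanced split,
    up getting the extra gene when n_de is odd).
    """
    import pandas as pd

    from rhabdosignal.transcriptomics import ExpressionMatrix

    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    reps = config.n_replicates
    samples = [f"treat_{i+1}" for i in range(reps)] + [f"ctrl_{i+1}" for i in range(reps)]
    groups = {s: ("treatment" if s.startswith("treat") else "control") for s in samples}

    base = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = base[:, None] + rng.normal(
        0.0, config.residual_sd, size=(config.n_genes, 2 * reps)
    )

    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    n_up = (config.n_de + 1) // 2
    truth: dict[str, str] = {}
    for rank, gi in enumerate(de_idx):
        sign = 1.0 if rank < n_up else -1.0
        values[gi, :reps] += sign * config.log_fc_effect
        truth[genes[gi]] = "up" if sign > 0 else "down"

    data = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(data=data, groups=groups), truth


__all__ = [
    "BRAND_NAMES",
    "CoAdeSpec",
    "DdiSpec",
    "CohortConfig",
    "CohortTruth",
    "generate_cohort",
    "write_faers_csv",
    "ExpressionConfig",
    "generate_expression",
]
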