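"""Published reference values for the statin--rhabdomyolysis contrasts.

2x2 cell counts and printed odds ratios from the published FAERS
disproportionality analysis that this package re-implements: all-report
contrasts vs simvastatin, monotherapy contrasts, and male-vs-female
contrasts per statin. The cells serve as fixed inputs for verifying the
odds-ratio machinery against the printed values.
"""

from __future__ import annotations

from typing import NamedTuple


class PublishedOR(NamedTuple):
    statin: str
    a: int  # exposure (or male) reports with the event
    b: int  # exposure (or male) reports without the event
    c: int  # reference (or female) reports with the event
    d: int  # reference (or female) reports without the event
    printed_or: float


# Each statin vs simvastatin (5030 with / 46416 without), all reports.
ALL_REPORTS = (
    PublishedOR("rosuvastatin", 2217, 53272, 5030, 46416, 0.3840),
    PublishedOR("atorvastatin", 3306, 98468, 5030, 46416, 0.3098),
    PublishedOR("pravastatin", 297, 12583, 5030, 46416, 0.2178),
    PublishedOR("lovastatin", 300, 15401, 5030, 46416, 0.1798),
)

# Each statin vs simvastatin (962 with / 11252 without), monotherapy reports.
MONOTHERAPY = (
    PublishedOR("rosuvastatin", 699, 17893, 962, 11252, 0.4569),
    PublishedOR("atorvastatin", 822, 35980, 962, 11252, 0.2672),
    PublishedOR("pravastatin", 65, 3618, 962, 11252, 0.2101),
    PublishedOR("lovastatin", 64, 7720, 962, 11252, 0.0970),
)

# Male vs female within each statin's reports.
SEX_CONTRAST = (
    PublishedOR("simvastatin", 3034, 21941, 1669, 20693, 1.7145),
    PublishedOR("rosuvastatin", 1138, 21896, 828, 27691, 1.7381),
    PublishedOR("atorvastatin", 1851, 39628, 1096, 47460, 2.0226),
    PublishedOR("pravastatin", 179, 5003, 91, 5860, 2.3040),
    PublishedOR("lovastatin", 155, 6186, 119, 6677, 1.4059),
)

# ORs whose printed p-value bound is "<0.0001"; the lovastatin sex contrast
# is excluded because its Woolf p is 0.0057 despite the printed bound.
BELOW_1E4 = tuple(
    row for group in (ALL_REPORTS, MONOTHERAPY, SEX_CONTRAST)
    for row in group
    if not (group is SEX_CONTRAST and row.statin == "lovastatin")
)

__all__ = ["PublishedOR", "ALL_REPORTS", "MONOTHERAPY", "SEX_CONTRAST", "BELOW_1E4"]
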