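"""Association-rule mining over spontaneous-report transactions.

Each report is one transaction whose items are namespaced drug and ADE
labels (``drug:furosemide``, ``ade:rhabdomyolysis``), keeping the two
universes disjoint. Rule metrics follow the classic market-basket
definitions:

    support(X -> Y)    = n(X and Y) / n_total
    confidence(X -> Y) = n(X and Y) / n(X)
    lift(X -> Y)       = support(X,Y) / (support(X) * support(Y))

Lift 1 means independence; the co-reported-ADE and DDI screens retain
rules with lift >= 1.5. Frequent itemsets are mined with a level-wise
Apriori using downward-closure pruning over a vertical (item -> case set)
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from rhabdosignal.errors import ArmError
from rhabdosignal.faers_io import AdverseEventReport, DrugSynonymMap, normalize_term

logger = logging.getLogger(__name__)

Itemset = frozenset[str]

DRUG_NS = "drug:"
ADE_NS = "ade:"


def drug_item(name: str) -> str:
    return DRUG_NS + name.strip().lower()


def ade_item(term: str) -> str:
    return ADE_NS + normalize_term(term)


@dataclass(frozen=True)
class Transaction:
    """One report as an itemset of namespaced drug/ADE labels."""

    items: Itemset
    source_case_id: str = ""

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("transaction items must be nonempty")


@dataclass(frozen=True)
class AssociationRule:
    """An X -> Y rule with its support, confidence and lift."""

    antecedent: Itemset
    consequent: Itemset
    support: float
    confidence: float
    lift: float
    count_xy: int


def reports_to_transactions(
    reports: Iterable[AdverseEventReport],
    include_drugs: bool = True,
    include_ades: bool = True,
    canonicalize: DrugSynonymMap | None = None,
) -> list[Transaction]:
    """Convert reports to transactions, skipping reports with no items.

    By default drug labels pass through untouched (so brand and generic
    rows stay distinct, as in dashboard exports); supply a synonym map to
    merge them.
    """
    transactions = []
    for report in reports:
        items: set[str] = set()
        if include_drugs:
            for d in report.drugs:
                if canonicalize is not None:
                    d = canonicalize.canonical(d)
                items.add(drug_item(d))
        if include_ades:
            items.update(ade_item(t) for t in report.ades)
        if items:
            transactions.append(Transaction(frozenset(items), report.case_id))
    return transactions


def _joint_count(transactions: Sequence[Transaction], items: Itemset) -> int:
    return sum(1 for t in transactions if items <= t.items)


def support(
    transactions: Sequence[Transaction], x: Itemset, y: Itemset = frozenset()
) -> float:
    """Fraction of transactions containing every item of X and of Y.

    With ``y`` empty this is the marginal support of X.
    """
    if not transactions:
        raise ArmError("support undefined on zero transactions")
    union = frozenset(x) | frozenset(y)
    if not union:
        raise ArmError("support of the empty itemset is undefined")
    return _joint_count(transactions, union) / len(transactions)


def confidence(transactions: Sequence[Transaction], x: Itemset, y: Itemset) -> float:
    """Joint count over antecedent count."""
    if not transactions:
        raise ArmError("confidence undefined on zero transactions")
    n_x = _joint_count(transactions, frozenset(x))
    if n_x == 0:
        raise ArmError(f"antecedent {set(x)} never occurs; confidence undefined")
    return _joint_count(transactions, frozenset(x) | frozenset(y)) / n_x


def lift(transactions: Sequence[Transaction], x: Itemset, y: Itemset) -> float:
    """support(X,Y) / (support(X) * support(Y)); symmetric in X and Y."""
    s_x = support(transactions, x)
    s_y = support(transactions, y)
    if s_x == 0.0 or s_y == 0.0:
        raise ArmError("zero marginal support; lift undefined")
    return support(transactions, x, y) / (s_x * s_y)


def mine_frequent_itemsets(
    transactions: Sequence[Transaction],
    min_support: float,
    max_size: int = 3,
) -> dict[Itemset, float]:
    """Level-wise Apriori: all itemsets of size <= max_size with support >= min_support.

    Candidates of size k are joined from frequent (k-1)-itemsets sharing a
    prefix and pruned when any (k-1)-subset is infrequent (downward
    closure); supports come from intersecting per-item transaction-id sets.
    """
    if not transactions:
        raise ArmError("cannot mine an empty transaction list")
    if not (0.0 < min_support <= 1.0):
        raise ValueError("min_support must be in (0, 1]")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")

    n = len(transactions)
    min_count = min_support * n
    tidsets: dict[str, set[int]] = {}
    for tid, t in enumerate(transactions):
        for item in t.items:
            tidsets.setdefault(item, set()).add(tid)

    result: dict[Itemset, float] = {}
    # level 1
    frequent: dict[Itemset, set[int]] = {}
    for item, tids in tidsets.items():
        if len(tids) >= min_count:
            iset = frozenset({item})
            frequent[iset] = tids
            result[iset] = len(tids) / n

    k = 2
    while frequent and k <= max_size:
        # join step on sorted-tuple prefixes
        prev = sorted(frequent, key=lambda s: tuple(sorted(s)))
        prev_set = set(frequent)
        candidates: dict[Itemset, set[int]] = {}
        for i, j in combinations(range(len(prev)), 2):
            a, b = tuple(sorted(prev[i])), tuple(sorted(prev[j]))
            if a[:-1] != b[:-1]:
                continue
            cand = prev[i] | prev[j]
            if len(cand) != k:
                continue
            # downward-closure prune
            if any(cand - {item} not in prev_set for item in cand):
                continue
            candidates[cand] = frequent[prev[i]] & frequent[prev[j]]
        frequent = {}
        for cand, tids in candidates.items():
            if len(tids) >= min_count:
                frequent[cand] = tids
                result[cand] = len(tids) / n
        k += 1
    return result


def _ranked_rules(
    rules: list[AssociationRule], lift_cutoff: float, k: int
) -> list[AssociationRule]:
    kept = [r for r in rules if r.lift >= lift_cutoff]
    kept.sort(
        key=lambda r: (-r.lift, -r.count_xy, tuple(sorted(r.antecedent | r.consequent)))
    )
    return kept[:k]


def co_reported_ades(
    reports: Sequence[AdverseEventReport],
    statin: str,
    target_event: str = "rhabdomyolysis",
    lift_cutoff: float = 1.5,
    k: int = 5,
    min_count: int = 10,
    within_subset: bool = True,
) -> list[AssociationRule]:
    """ADEs that co-report with the target event among a statin's reports.

    For every other ADE term ``e`` the lift between ``{ade:target}`` and
    ``{ade:e}`` is computed inside the statin's report subset (the
    conditioning universe; set ``within_subset=False`` to use the whole
    corpus with the statin folded into the antecedent). Rules with lift >=
    ``lift_cutoff`` and joint count >= ``min_count`` are ranked by
    descending lift (ties: joint count, then alphabetical) and the top
    ``k`` returned.
    """
    target = ade_item(target_event)
    subset = [r for r in reports if statin in r.drugs]
    universe = subset if within_subset else list(reports)
    # drug items are kept so that ADE-free reports still count in the
    # denominator: the conditioning universe is the whole report subset
    transactions = reports_to_transactions(universe)
    if not transactions:
        logger.warning("no transactions for statin %r", statin)
        return []
    n = len(transactions)
    x_items = frozenset({target} if within_subset else {target, drug_item(statin)})
    n_x = _joint_count(transactions, x_items)
    if n_x == 0:
        logger.warning("target event %r absent for statin %r", target_event, statin)
        return []

    terms = sorted({item for t in transactions for item in t.items
                    if item.startswith(ADE_NS) and item != target})
    rules = []
    for term in terms:
        n_y = len([t for t in transactions if term in t.items])
        n_xy = _joint_count(transactions, x_items | {term})
        if n_xy < min_count:
            continue
        rules.append(
            AssociationRule(
                antecedent=x_items,
                consequent=frozenset({term}),
                support=n_xy / n,
                confidence=n_xy / n_x,
                lift=(n_xy / n) / ((n_x / n) * (n_y / n)),
                count_xy=n_xy,
            )
        )
    return _ranked_rules(rules, lift_cutoff, k)


def ddi_rules(
    reports: Sequence[AdverseEventReport],
    statin: str,
    target_event: str = "rhabdomyolysis",
    lift_cutoff: float = 1.5,
    k: int = 10,
    min_count: int = 10,
) -> list[AssociationRule]:
    """Drug--drug-interaction candidate rules {statin, comedication} -> target event.

    Within the statin's report subset, each co-medication ``g`` yields the
    rule ``{drug:statin, drug:g} -> {ade:target}``; rules with lift >=
    ``lift_cutoff`` (and joint count >= ``min_count``, to suppress
    single-report noise) are ranked by descending lift, top ``k`` kept.
    """
    target = ade_item(target_event)
    statin_item = drug_item(statin)
    subset = [r for r in reports if statin in r.drugs]
    transactions = reports_to_transactions(subset)
    if not transactions:
        logger.warning("no transactions for statin %r", statin)
        return []
    n = len(transactions)
    n_t = len([t for t in transactions if target in t.items])
    if n_t == 0:
        logger.warning("target event %r absent for statin %r", target_event, statin)
        return []

    comeds = sorted({item for t in transactions for item in t.items
                     if item.startswith(DRUG_NS) and item != statin_item})
    rules = []
    for g in comeds:
        x_items = frozenset({statin_item, g})
        n_x = _joint_count(transactions, x_items)
        if n_x == 0:
            continue
        n_xy = _joint_count(transactions, x_items | {target})
        if n_xy < min_count:
            continue
        rules.append(
            AssociationRule(
                antecedent=x_items,
                consequent=frozenset({target}),
                support=n_xy / n,
                confidence=n_xy / n_x,
                lift=(n_xy / n) / ((n_x / n) * (n_t / n)),
                count_xy=n_xy,
            )
        )
    return _ranked_rules(rules, lift_cutoff, k)


def write_transactions(transactions: Iterable[Transaction], path) -> None:
    """One transaction per line, namespaced items space-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in transactions:
            fh.write(" ".join(sorted(t.items)) + "\n")


def rules_to_records(rules: Iterable[AssociationRule]) -> list[dict]:
    """Flatten rules for CSV output (lift rendered at full precision)."""
    return [
        {
            "antecedent": ";".join(sorted(r.antecedent)),
            "consequent": ";".join(sorted(r.consequent)),
            "count_xy": r.count_xy,
            "support": r.support,
            "confidence": r.confidence,
            "lift": r.lift,
        }
        for r in rules
    ]


__all__ = [
    "Transaction",
    "AssociationRule",
    "drug_item",
    "ade_item",
    "reports_to_transactions",
    "support",
    "confidence",
    "lift",
    "mine_frequent_itemsets",
    "co_reported_ades",
    "ddi_rules",
    "write_transactions",
    "rules_to_records",
]
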