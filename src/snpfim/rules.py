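"""Association rules between parts of a frequent itemset.

The strength of a rule A -> B is its confidence: the support of the
transactions containing both A and B, divided by the support of A — i.e.
the conditional frequency of B among the transactions where A occurs.
Supports are always recomputed on the transaction database the itemsets
were mined from, in integer counts, so confidence is an exact rational.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import pandas as pd

from .fpm import MiningResult
from .transactions import TransactionDB

__all__ = [
    "AssociationRule",
    "confidence",
    "display_confidence",
    "generate_rules",
    "rule_chain",
    "rules_table",
]


def confidence(support_ab: float, support_a: float) -> float:
    """Confidence(A -> B) = Support(A and B) / Support(A).

    Both arguments may be rates or raw counts, as long as they share a
    denominator. Exact value; see :func:`display_confidence` for the
    2-decimal report rounding.
    """
    if support_a <= 0:
        raise ValueError("confidence undefined: Support(A) must be positive")
    if support_ab < 0:
        raise ValueError("Support(A and B) cannot be negative")
    if support_ab > support_a:
        raise ValueError(
            f"inconsistent supports: Support(A and B)={support_ab} exceeds "
            f"Support(A)={support_a}"
        )
    return support_ab / support_a


def display_confidence(value: float) -> str:
    """Round half-up to 2 decimals for report tables (0.985 -> '0.99');
    internal values are never rounded."""
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssociationRule:
    """A -> B with supports as rates of the source transaction DB."""

    antecedent: tuple
    consequent: tuple
    support_a: float
    support_ab: float
    confidence: float
    meets_min_confidence: bool

    def __post_init__(self):
        if set(self.antecedent) & set(self.consequent):
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def display(self) -> str:
        return display_confidence(self.confidence)

    def __str__(self) -> str:
        return (
            f"{', '.join(self.antecedent)} -> {', '.join(self.consequent)} "
            f"[conf {self.display}]"
        )


def _splits(items: tuple, policy: str):
    """Yield (antecedent, consequent) pairs for one frequent itemset."""
    k = len(items)
    if policy == "single-consequent":
        # every (k-1)-item antecedent -> the remaining single item; for
        # k = 2 this is exactly both directions of the pair
        for x in items:
            yield tuple(it for it in items if it != x), (x,)
    elif policy == "powerset":
        for r in range(1, k):
            for ante in combinations(items, r):
                yield ante, tuple(it for it in items if it not in ante)
    else:
        raise ValueError(f"unknown antecedent policy {policy!r}")


def generate_rules(
    mining_result: MiningResult,
    td: TransactionDB,
    min_confidence: float = 0.8,
    antecedent_policy: str = "single-consequent",
) -> list:
    """Rules from every frequent itemset of size >= 2.

    Rules below ``min_confidence`` are flagged (``meets_min_confidence``
    False), not dropped, so report tables can print them as "--" the way
    low-confidence chain steps are conventionally shown.
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must be in [0, 1]")
    rules = []
    td_num = td.td_num
    for fi in mining_result.itemsets:
        if fi.k < 2:
            continue
        count_ab = td.support(fi.items)
        if count_ab != fi.support:
            raise ValueError(
                f"itemset {fi.items} support {fi.support} does not match the "
                f"transaction DB (recomputed {count_ab}); wrong TD?"
            )
        if count_ab == 0:
            raise ValueError(f"itemset {fi.items} is not frequent in the DB")
        for ante, cons in _splits(fi.items, antecedent_policy):
            count_a = td.support(ante)
            conf = confidence(count_ab, count_a)
            rules.append(
                AssociationRule(
                    antecedent=ante,
                    consequent=cons,
                    support_a=count_a / td_num,
                    support_ab=count_ab / td_num,
                    confidence=conf,
                    meets_min_confidence=conf >= min_confidence,
                )
            )
    rules.sort(
        key=lambda r: (len(r.antecedent) + len(r.consequent), -r.confidence,
                       r.antecedent, r.consequent)
    )
    return rules


def rule_chain(items, td: TransactionDB, min_confidence: float = 0.8) -> list:
    """Prefix chain over one itemset: for the sorted items (i1..ik), the
    rules (i1) -> i2, (i1, i2) -> i3, ..., (i1..ik-1) -> ik."""
    items = tuple(sorted(items))
    rules = []
    for k in range(1, len(items)):
        ante, cons = items[:k], (items[k],)
        count_a = td.support(ante)
        count_ab = td.support(ante + cons)
        conf = confidence(count_ab, count_a)
        rules.append(
            AssociationRule(
                antecedent=ante,
                consequent=cons,
                support_a=count_a / td.td_num,
                support_ab=count_ab / td.td_num,
                confidence=conf,
                meets_min_confidence=conf >= min_confidence,
            )
        )
    return rules


def rules_table(rules) -> pd.DataFrame:
    """Tidy table: full-precision confidence plus the 2-dp display column;
    sub-threshold rules display as '--'."""
    return pd.DataFrame(
        {
            "antecedent": [";".join(r.antecedent) for r in rules],
            "consequent": [";".join(r.consequent) for r in rules],
            "support_a": [r.support_a for r in rules],
            "support_ab": [r.support_ab for r in rules],
            "confidence": [r.confidence for r in rules],
            "display": [r.display if r.meets_min_confidence else "--" for r in rules],
            "meets_min_confidence": [r.meets_min_confidence for r in rules],
        }
    )
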