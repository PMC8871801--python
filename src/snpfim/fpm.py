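"""Frequent-itemset mining over the transactional dataset.

Two production miners — FP-Growth (compressed prefix tree with per-item
pointer chains and recursive conditional trees) and Eclat (vertical
transaction-id sets with recursive intersection) — plus a deliberately
naive level-wise Apriori used as an independent oracle in equivalence
tests. All three must return the same (itemset, support) collection.

Threshold semantics: an itemset is frequent iff support_rate >= s. The
comparison is done in exact rational arithmetic (support/td_num >= s as
Fractions), never in floating point, so boundary cases like s = 0.6 on
3/5 cannot drift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import pandas as pd

from .transactions import TransactionDB

__all__ = [
    "FrequentItemset",
    "MiningResult",
    "fp_growth",
    "eclat",
    "apriori_oracle",
    "count_by_size",
]


@dataclass(frozen=True)
class FrequentItemset:
    """An itemset with its support count and rate in the mined DB."""

    items: tuple  # sorted item identifiers
    support: int
    support_rate: float

    @property
    def k(self) -> int:
        return len(self.items)


@dataclass
class MiningResult:
    algorithm: str
    s: float
    td_num: int
    itemsets: list

    def __post_init__(self):
        # deterministic report order: by size, then descending support,
        # then lexicographic items
        self.itemsets = sorted(
            self.itemsets, key=lambda fi: (fi.k, -fi.support, fi.items)
        )
        seen = set()
        for fi in self.itemsets:
            if fi.items in seen:
                raise ValueError(f"duplicate itemset {fi.items}")
            seen.add(fi.items)

    def counts_by_k(self) -> dict:
        counts: dict = {}
        for fi in self.itemsets:
            counts[fi.k] = counts.get(fi.k, 0) + 1
        return counts

    def as_sets(self) -> set:
        """Canonical (frozenset, support) pairs for cross-algorithm checks."""
        return {(frozenset(fi.items), fi.support) for fi in self.itemsets}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "items": [";".join(fi.items) for fi in self.itemsets],
                "k": [fi.k for fi in self.itemsets],
                "support": [fi.support for fi in self.itemsets],
                "support_rate": [fi.support_rate for fi in self.itemsets],
            }
        )

    def top(self, k: int, n: int = 5) -> list:
        """Top-n k-item itemsets by support rate (report tables)."""
        return [fi for fi in self.itemsets if fi.k == k][:n]


def _min_count(s: float, td_num: int) -> int:
    """Smallest integer support c with c / td_num >= s, computed exactly."""
    if not 0 < s <= 1:
        raise ValueError("support-rate threshold s must be in (0, 1]")
    return max(1, math.ceil(Fraction(s) * td_num))


def _result(algorithm, s, td, found) -> MiningResult:
    td_num = td.td_num
    itemsets = [
        FrequentItemset(items=tuple(sorted(items)), support=c, support_rate=c / td_num)
        for items, c in found
    ]
    return MiningResult(algorithm=algorithm, s=s, td_num=td_num, itemsets=itemsets)


# --------------------------------------------------------------------------
# FP-Growth
# --------------------------------------------------------------------------


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children = {}


class _FPTree:
    """Prefix tree over frequency-ordered transactions.

    ``header[item]`` is the chain of pointers threading every node carrying
    that item; the sum of their counts is the item's support among the
    tree's transactions.
    """

    def __init__(self, weighted_transactions, min_count):
        counts: dict = {}
        for items, w in weighted_transactions:
            for it in items:
                counts[it] = counts.get(it, 0) + w
        self.counts = {it: c for it, c in counts.items() if c >= min_count}
        # insertion order: descending support, ties broken lexicographically
        self.order = {
            it: r
            for r, it in enumerate(
                sorted(self.counts, key=lambda it: (-self.counts[it], it))
            )
        }
        self.root = _FPNode(None, None)
        self.header: dict = {it: [] for it in self.counts}
        for items, w in weighted_transactions:
            keep = sorted(
                (it for it in items if it in self.counts), key=self.order.__getitem__
            )
            node = self.root
            for it in keep:
                child = node.children.get(it)
                if child is None:
                    child = _FPNode(it, node)
                    node.children[it] = child
                    self.header[it].append(child)
                child.count += w
                node = child

    def is_empty(self) -> bool:
        return not self.root.children

    def single_path(self):
        """Return the node list if the tree is a single path, else None."""
        path = []
        node = self.root
        while len(node.children) == 1:
            node = next(iter(node.children.values()))
            path.append(node)
        return path if not node.children else None

    def prefix_path(self, node):
        items = []
        node = node.parent
        while node.item is not None:
            items.append(node.item)
            node = node.parent
        return items


def fp_growth(td: TransactionDB, s: float) -> MiningResult:
    """Mine all itemsets with support_rate >= s via FP-Growth.

    Conditional trees are processed from an explicit work stack (not Python
    recursion): item universes of a few thousand SNPs can produce deep
    conditional chains.
    """
    min_count = _min_count(s, td.td_num)
    found = []
    root_tree = _FPTree([(t, 1) for t in td.transactions], min_count)
    stack = [(root_tree, ())]
    while stack:
        tree, suffix = stack.pop()
        path = tree.single_path()
        if path is not None:
            # single-path shortcut: every subset of the path, support of a
            # subset = count of its deepest (lowest-count) node
            for r in range(1, len(path) + 1):
                for combo in combinations(path, r):
                    found.append(
                        (tuple(n.item for n in combo) + suffix, combo[-1].count)
                    )
            continue
        # process header items in ascending frequency order
        for item in sorted(tree.counts, key=lambda it: (tree.counts[it], it)):
            new_suffix = (item,) + suffix
            found.append((new_suffix, tree.counts[item]))
            # conditional pattern base P_i: prefix paths of the pointer chain
            base = [
                (tree.prefix_path(node), node.count)
                for node in tree.header[item]
                if node.parent.item is not None
            ]
            if not base:
                continue
            cond = _FPTree(base, min_count)
            if not cond.is_empty():
                stack.append((cond, new_suffix))
    return _result("fpgrowth", s, td, found)


# --------------------------------------------------------------------------
# Eclat
# --------------------------------------------------------------------------


def eclat(td: TransactionDB, s: float) -> MiningResult:
    """Mine all itemsets with support_rate >= s via Eclat.

    Each item carries its vertical tidset (set of transaction indices);
    the tidset of a union of items is the intersection of their tidsets.
    Equivalence classes are processed from an explicit work stack.
    """
    min_count = _min_count(s, td.td_num)
    tidsets: dict = {}
    for tid, items in enumerate(td.transactions):
        for it in items:
            tidsets.setdefault(it, set()).add(tid)
    first = sorted(
        ((it, frozenset(tids)) for it, tids in tidsets.items() if len(tids) >= min_count)
    )
    found = []
    stack = [((), first)]
    while stack:
        prefix, klass = stack.pop()
        for i, (item, tids) in enumerate(klass):
            new_prefix = prefix + (item,)
            found.append((new_prefix, len(tids)))
            sub = []
            for other, other_tids in klass[i + 1 :]:
                inter = tids & other_tids
                if len(inter) >= min_count:
                    sub.append((other, inter))
            if sub:
                stack.append((new_prefix, sub))
    return _result("eclat", s, td, found)


# --------------------------------------------------------------------------
# Apriori oracle
# --------------------------------------------------------------------------


def apriori_oracle(td: TransactionDB, s: float, max_items: int = 25) -> MiningResult:
    """Level-wise Apriori: candidate join + subset pruning + full DB scans.

    Kept deliberately simple as the independent ground truth for testing the
    production miners; intended for small item universes.
    """
    min_count = _min_count(s, td.td_num)
    active = {it for t in td.transactions for it in t}
    if len(active) > max_items:
        warnings.warn(
            f"apriori_oracle on {len(active)} distinct items may be very slow",
            stacklevel=2,
        )
    found = []
    level = {}
    for it in sorted(active):
        c = sum(1 for t in td.transactions if it in t)
        if c >= min_count:
            level[(it,)] = c
    while level:
        found.extend(level.items())
        prev = set(level)
        candidates = set()
        keys = sorted(prev)
        for a, b in combinations(keys, 2):
            if a[:-1] == b[:-1]:
                cand = a + (b[-1],)
                if all(
                    tuple(sub) in prev for sub in combinations(cand, len(cand) - 1)
                ):
                    candidates.add(cand)
        level = {}
        for cand in candidates:
            cset = frozenset(cand)
            c = sum(1 for t in td.transactions if cset <= t)
            if c >= min_count:
                level[cand] = c
    return _result("apriori", s, td, found)


ALGORITHMS = {"fpgrowth": fp_growth, "eclat": eclat, "apriori": apriori_oracle}


def count_by_size(result: MiningResult) -> dict:
    """Number of mined itemsets per item count k."""
    return result.counts_by_k()
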