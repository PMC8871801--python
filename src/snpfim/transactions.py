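"""Transactional view of the p-value matrix: voxels are transactions,
significant SNPs are items.

A SNP l_i is an item of voxel v's transaction iff P(l_i) <= alpha at v
(inclusive threshold; the indicator is written with <=, and this module
keeps that convention to avoid </<= drift). Support of an itemset is the
number of transactions containing all of its items; the support rate is
that count divided by TD_num, the total number of transactions. Empty
transactions are retained so support rates keep the full-ROI denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransactionDB",
    "ROIMap",
    "build_transactions",
    "support",
    "support_rate",
    "subset_by_roi",
]


@dataclass(frozen=True)
class ROIMap:
    """voxel identifier -> anatomical region label (one atlas level)."""

    mapping: dict

    def labels(self):
        return sorted(set(self.mapping.values()))

    def voxels(self, label: str):
        return [v for v, lab in self.mapping.items() if lab == label]

    def __getitem__(self, voxel):
        return self.mapping[voxel]

    @classmethod
    def from_tsv(cls, path) -> "ROIMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"voxel_id": list(self.mapping), "label": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class TransactionDB:
    """The transactional dataset TD.

    ``transactions[k]`` is the set of item (SNP) identifiers significant at
    voxel ``voxel_ids[k]``. ``td_num`` counts all transactions, including
    empty ones. ``items`` is the item universe (the source matrix's SNP
    list), which bounds what may be queried.
    """

    voxel_ids: list
    transactions: list  # list of frozenset of item ids
    alpha: float
    items: tuple = ()

    def __post_init__(self):
        self.transactions = [frozenset(t) for t in self.transactions]
        if not self.items:
            universe = set()
            for t in self.transactions:
                universe |= t
            self.items = tuple(sorted(universe))
        seen = set(self.items)
        for t in self.transactions:
            if not t <= seen:
                raise ValueError(
                    f"transaction items {sorted(t - seen)} missing from item universe"
                )

    @property
    def td_num(self) -> int:
        return len(self.transactions)

    def _check_itemset(self, itemset) -> frozenset:
        items = frozenset(itemset)
        if not items:
            raise ValueError("itemset must be non-empty")
        unknown = items - set(self.items)
        if unknown:
            raise KeyError(f"unknown item(s): {sorted(unknown)}")
        return items

    def support(self, itemset) -> int:
        """Number of transactions containing every item of ``itemset``."""
        items = self._check_itemset(itemset)
        return sum(1 for t in self.transactions if items <= t)

    def support_rate(self, itemset) -> float:
        return self.support(itemset) / self.td_num

    def item_supports(self) -> pd.DataFrame:
        """Per-item support and support rate, sorted by descending rate."""
        rows = [
            {"item": it, "support": self.support([it]),
             "support_rate": self.support_rate([it])}
            for it in self.items
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["support_rate", "item"], ascending=[False, True]
        ).reset_index(drop=True)

    # --- FIMI basket format: one whitespace-separated line per transaction ---
    def to_basket(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.transactions:
                fh.write(" ".join(sorted(t)) + "\n")

    @classmethod
    def from_basket(cls, path, alpha: float = float("nan")) -> "TransactionDB":
        transactions = []
        with open(path) as fh:
            for line in fh:
                transactions.append(frozenset(line.split()))
        return cls(
            voxel_ids=[f"t{k}" for k in range(len(transactions))],
            transactions=transactions,
            alpha=alpha,
        )


def build_transactions(
    pvals: pd.DataFrame,
    alpha: float = 0.05,
    voxel_subset=None,
    fdr: bool = False,
) -> TransactionDB:
    """Threshold the SNP x voxel p-value matrix into a TransactionDB.

    No multiple-testing correction is applied by default: downstream
    frequency-of-occurrence filtering is what controls spurious items. Set
    ``fdr=True`` to Benjamini-Hochberg-adjust all cells first.

    Empty transactions (voxels where no SNP is significant) are retained;
    they still count in td_num.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if voxel_subset is not None:
        voxel_subset = list(voxel_subset)
        if not voxel_subset:
            raise ValueError("voxel_subset must be non-empty")
        missing = set(voxel_subset) - set(pvals.columns)
        if missing:
            raise KeyError(f"voxels not in matrix: {sorted(missing)}")
        pvals = pvals[voxel_subset]
    mat = pvals.to_numpy(dtype=float)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        flat = mat.ravel()
        _, adj, _, _ = multipletests(flat, method="fdr_bh")
        mat = adj.reshape(mat.shape)
    sig = mat <= alpha
    snps = np.asarray(pvals.index)
    transactions = [frozenset(snps[sig[:, c]]) for c in range(sig.shape[1])]
    return TransactionDB(
        voxel_ids=list(pvals.columns),
        transactions=transactions,
        alpha=alpha,
        items=tuple(pvals.index),
    )


def support(td: TransactionDB, itemset) -> int:
    return td.support(itemset)


def support_rate(td: TransactionDB, itemset) -> float:
    return td.support_rate(itemset)


def subset_by_roi(pvals: pd.DataFrame, roi_map: ROIMap, label: str) -> pd.DataFrame:
    """Restrict the p-value matrix to the voxels of one ROI, preserving SNP
    rows and the matrix's voxel order."""
    available = roi_map.labels()
    if label not in available:
        raise KeyError(f"unknown ROI label {label!r}; available: {available}")
    keep = [v for v in pvals.columns if roi_map.mapping.get(v) == label]
    if not keep:
        raise ValueError(f"ROI {label!r} has no voxels in the matrix")
    return pvals[keep]
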