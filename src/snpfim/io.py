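"""TSV/JSON readers and writers for the pipeline's artifacts.

All matrices are tab-separated with a header row and the row-identifier in
the first column; every writer here round-trips through its reader to an
equal in-memory object.
"""

from __future__ import annotations

import json

import pandas as pd

from .fpm import FrequentItemset, MiningResult

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_mining_tsv",
    "read_mining_tsv",
    "write_mining_json",
    "read_mining_json",
]


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_mining_tsv(result: MiningResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def read_mining_tsv(path, algorithm: str = "", s: float = float("nan"),
                    td_num: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mining_json(result: MiningResult, path) -> None:
    payload = {
        "algorithm": result.algorithm,
        "s": result.s,
        "td_num": result.td_num,
        "counts_by_k": {str(k): v for k, v in sorted(result.counts_by_k().items())},
        "itemsets": [
            {"items": list(fi.items), "support": fi.support,
             "support_rate": fi.support_rate}
            for fi in result.itemsets
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_mining_json(path) -> MiningResult:
    with open(path) as fh:
        payload = json.load(fh)
    return MiningResult(
        algorithm=payload["algorithm"],
        s=payload["s"],
        td_num=payload["td_num"],
        itemsets=[
            FrequentItemset(
                items=tuple(d["items"]), support=d["support"],
                support_rate=d["support_rate"],
            )
            for d in payload["itemsets"]
        ],
    )
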