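"""ROI activation by a frequent SNP: the top-fraction voxel criterion.

An ROI is declared *activated* by a SNP when the top 20% of its voxels —
ranked by per-voxel association strength for that SNP, descending — are
all significant (p <= alpha). The ranking score is -log10(p) of the SNP's
association at the voxel (monotone in the squared t-statistic), which is
the per-voxel SNP-specific signal the pipeline possesses; ties are broken
by voxel identifier so runs are deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transactions import ROIMap

__all__ = ["ROIActivation", "ActivationResult", "activated_rois", "activation_table"]


@dataclass(frozen=True)
class ROIActivation:
    label: str
    n_voxels: int
    n_top: int
    top_voxels: tuple  # ranked, best first
    top_pvalues: tuple
    activated: bool


@dataclass
class ActivationResult:
    snp_id: str
    top_frac: float
    alpha: float
    rois: list  # of ROIActivation

    def activated_labels(self) -> list:
        return [r.label for r in self.rois if r.activated]


def activated_rois(
    pvals: pd.DataFrame,
    roi_map: ROIMap,
    snp_id: str,
    top_frac: float = 0.2,
    alpha: float = 0.05,
    ranking: str = "significance",
    strict: bool = False,
) -> ActivationResult:
    """Evaluate the top-fraction activation criterion for one SNP over every
    ROI of the map.

    Parameters
    ----------
    top_frac : fraction of each ROI's voxels kept after ranking; the count
        is ceil(top_frac * n), so tiny ROIs keep at least one voxel.
    alpha : significance level for the kept voxels.
    ranking : 'significance' ranks voxels by -log10(p), descending.
    strict : use p < alpha instead of the default inclusive p <= alpha.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if ranking != "significance":
        raise ValueError(f"unknown ranking {ranking!r}")
    if snp_id not in pvals.index:
        raise KeyError(f"SNP {snp_id!r} not in the p-value matrix")
    row = pvals.loc[snp_id]
    rois = []
    for label in roi_map.labels():
        voxels = [v for v in pvals.columns if roi_map.mapping.get(v) == label]
        if not voxels:
            warnings.warn(f"ROI {label!r} has no voxels in the matrix; skipped",
                          stacklevel=2)
            continue
        p = row[voxels].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            score = -np.log10(np.maximum(p, 0.0))
        ranked = sorted(zip(voxels, p, score), key=lambda t: (-t[2], t[0]))
        n_top = math.ceil(top_frac * len(voxels))
        top = ranked[:n_top]
        if strict:
            ok = all(pv < alpha for _, pv, _ in top)
        else:
            ok = all(pv <= alpha for _, pv, _ in top)
        rois.append(
            ROIActivation(
                label=label,
                n_voxels=len(voxels),
                n_top=n_top,
                top_voxels=tuple(v for v, _, _ in top),
                top_pvalues=tuple(float(pv) for _, pv, _ in top),
                activated=ok,
            )
        )
    return ActivationResult(snp_id=snp_id, top_frac=top_frac, alpha=alpha, rois=rois)


def activation_table(result: ActivationResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [result.snp_id] * len(result.rois),
            "roi": [r.label for r in result.rois],
            "n_voxels": [r.n_voxels for r in result.rois],
            "n_top": [r.n_top for r in result.rois],
            "min_top_p": [min(r.top_pvalues) for r in result.rois],
            "max_top_p": [max(r.top_pvalues) for r in result.rois],
            "activated": [r.activated for r in result.rois],
        }
    )
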