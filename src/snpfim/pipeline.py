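"""End-to-end pipeline driver and paper-style reports.

``run_pipeline`` takes one :class:`PipelineConfig` and produces the full
artifact set: the p-value matrix, per-ROI transaction baskets, mining
results per (ROI, s), rule tables, the activation report, the threshold
sweep, and a JSON manifest that echoes every parameter so a run can be
reproduced from the manifest alone. All randomness flows through the
single config seed; deterministic stages are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .activation import activated_rois, activation_table
from .fpm import ALGORITHMS, MiningResult
from .io import write_matrix_tsv, write_mining_json, write_mining_tsv
from .rules import generate_rules, rules_table
from .simulate import SimConfig, simulate_dataset
from .transactions import ROIMap, build_transactions, subset_by_roi
from .vgwas import hwe_filter, run_vgwas

__all__ = ["PipelineConfig", "run_pipeline", "sweep_report"]

log = logging.getLogger("snpfim")


@dataclass
class PipelineConfig:
    """Everything one run needs: either a simulation block or input paths,
    plus thresholds and output location."""

    outdir: str
    seed: int = 0
    alpha: float = 0.05
    s_grid: list = field(default_factory=lambda: [0.3, 0.5, 0.7])
    algorithm: str = "eclat"
    min_confidence: float = 0.8
    top_frac: float = 0.2
    hwe_threshold: float = 1e-6
    roi_labels: list | None = None  # None = all labels of the map
    activation_snp: str | None = None  # None = top-support item of first ROI
    # either simulate ...
    simulation: dict | None = None
    sim_rois: dict | None = None  # label -> voxel count, consecutive
    # ... or load
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    covariates_path: str | None = None
    pvalues_path: str | None = None
    roi_map_path: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for s in self.s_grid:
            if not 0 < s <= 1:
                raise ValueError(f"support threshold {s} out of (0, 1]")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must be in [0, 1]")
        has_inputs = self.pvalues_path or (self.genotypes_path and self.phenotypes_path)
        if self.simulation is None and not has_inputs:
            raise ValueError(
                "config needs a simulation block, a pvalues_path, or "
                "genotypes_path + phenotypes_path"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        return d


def _default_roi_map(voxels, sim_rois: dict | None) -> ROIMap:
    """Assign the matrix's voxels to labels in consecutive runs."""
    voxels = list(voxels)
    if not sim_rois:
        sim_rois = {"ROI_1": len(voxels)}
    mapping = {}
    v = 0
    for label, count in sim_rois.items():
        if v + count > len(voxels):
            raise ValueError("sim_rois voxel counts exceed the matrix's voxels")
        for _ in range(count):
            mapping[voxels[v]] = label
            v += 1
    for w in range(v, len(voxels)):
        mapping[voxels[w]] = "UNASSIGNED"
    return ROIMap(mapping)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return {artifact name: path}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    # ---- stage 1: obtain the p-value matrix -------------------------------
    if config.pvalues_path:
        log.info("loading p-value matrix from %s", config.pvalues_path)
        from .io import read_matrix_tsv

        pvals = read_matrix_tsv(config.pvalues_path)
    else:
        if config.simulation is not None:
            sim = SimConfig(seed=config.seed, **config.simulation)
            log.info(
                "simulating dataset: %d subjects, %d SNPs, %d voxels, %d block(s)",
                sim.n_subjects, sim.n_snps, sim.n_voxels, len(sim.blocks),
            )
            genotypes, covariates, phenotypes = simulate_dataset(sim)
            write_matrix_tsv(genotypes, out / "genotypes.tsv", "subject_id")
            write_matrix_tsv(phenotypes, out / "phenotypes.tsv", "subject_id")
            write_matrix_tsv(covariates, out / "covariates.tsv", "subject_id")
            paths.update(
                genotypes=str(out / "genotypes.tsv"),
                phenotypes=str(out / "phenotypes.tsv"),
                covariates=str(out / "covariates.tsv"),
            )
        else:
            from .io import read_matrix_tsv

            genotypes = read_matrix_tsv(config.genotypes_path)
            phenotypes = read_matrix_tsv(config.phenotypes_path)
            covariates = (
                read_matrix_tsv(config.covariates_path)
                if config.covariates_path
                else None
            )
        kept, _ = hwe_filter(genotypes, config.hwe_threshold)
        dropped = genotypes.shape[1] - len(kept)
        if dropped:
            log.info("HWE filter removed %d SNP(s)", dropped)
        genotypes = genotypes[kept]
        cov = covariates if covariates is not None and covariates.shape[1] else None
        log.info("vGWAS: %d SNPs x %d voxels", genotypes.shape[1], phenotypes.shape[1])
        pvals = run_vgwas(genotypes, phenotypes, cov)
    write_matrix_tsv(pvals, out / "pvalues.tsv", "snp_id")
    paths["pvalues"] = str(out / "pvalues.tsv")

    # ---- stage 2: ROI map -------------------------------------------------
    if config.roi_map_path:
        roi_map = ROIMap.from_tsv(config.roi_map_path)
    else:
        roi_map = _default_roi_map(pvals.columns, config.sim_rois)
    roi_map.to_tsv(out / "roi_map.tsv")
    paths["roi_map"] = str(out / "roi_map.tsv")
    labels = config.roi_labels or roi_map.labels()

    # ---- stages 3-6 per ROI ----------------------------------------------
    mine = ALGORITHMS[config.algorithm]
    for label in labels:
        roi_pvals = subset_by_roi(pvals, roi_map, label)
        td = build_transactions(roi_pvals, config.alpha)
        log.info("ROI %s: TD_num = %d", label, td.td_num)
        td.to_basket(out / f"transactions_{label}.basket")
        paths[f"transactions_{label}"] = str(out / f"transactions_{label}.basket")
        results = []
        for s in config.s_grid:
            result = mine(td, s)
            results.append(result)
            log.info("ROI %s, s=%g: %d FIs %s", label, s,
                     len(result.itemsets), result.counts_by_k())
            stem = f"{label}_s{s:g}"
            write_mining_tsv(result, out / f"itemsets_{stem}.tsv")
            write_mining_json(result, out / f"itemsets_{stem}.json")
            paths[f"itemsets_{stem}"] = str(out / f"itemsets_{stem}.tsv")
            rules = generate_rules(result, td, config.min_confidence)
            rules_table(rules).to_csv(out / f"rules_{stem}.tsv", sep="\t", index=False)
            paths[f"rules_{stem}"] = str(out / f"rules_{stem}.tsv")
        sweep = sweep_report(results)
        sweep.to_csv(out / f"sweep_{label}.tsv", sep="\t", index=False)
        paths[f"sweep_{label}"] = str(out / f"sweep_{label}.tsv")

    # ---- stage 7: activation ---------------------------------------------
    snp = config.activation_snp
    if snp is None:
        first_td = build_transactions(
            subset_by_roi(pvals, roi_map, labels[0]), config.alpha
        )
        supports = first_td.item_supports()
        snp = supports.iloc[0]["item"] if len(supports) else pvals.index[0]
    act = activated_rois(pvals, roi_map, snp, config.top_frac, config.alpha)
    activation_table(act).to_csv(out / "activation.tsv", sep="\t", index=False)
    paths["activation"] = str(out / "activation.tsv")
    log.info("SNP %s activates %d ROI(s)", snp, len(act.activated_labels()))

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "snpfim_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "activation_snp": snp,
        "artifacts": paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    paths["manifest"] = str(out / "manifest.json")
    return paths


def sweep_report(results) -> pd.DataFrame:
    """Long-format (s, k, count) table across mining runs of one TD.

    Every k observed at any s appears at every s (explicit zeros), so the
    FI-count-versus-threshold curves plot without gaps.
    """
    if not results:
        raise ValueError("no mining results to report")
    td_nums = {r.td_num for r in results}
    if len(td_nums) > 1:
        raise ValueError(f"results come from different TDs (td_num in {sorted(td_nums)})")
    max_k = max((fi.k for r in results for fi in r.itemsets), default=1)
    rows = []
    for r in sorted(results, key=lambda r: r.s):
        counts = r.counts_by_k()
        for k in range(1, max_k + 1):
            rows.append({"s": r.s, "k": k, "count": counts.get(k, 0)})
    return pd.DataFrame(rows)
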