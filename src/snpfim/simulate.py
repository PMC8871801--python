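"""Synthetic imaging-genetics data with planted multi-SNP / multi-voxel effects.

Real studies of this kind pair genotype dosages with voxelwise gray-matter
density maps; both are access-restricted. This module emulates the joint
structure those data need to exercise every downstream stage:

* genotypes drawn in Hardy-Weinberg proportions at chosen minor-allele
  frequencies,
* voxel phenotypes carrying additive effects of planted SNP blocks on
  overlapping voxel sets, so the planted SNP groups become co-significant
  frequent itemsets after mass-univariate association,
* a direct p-value-matrix shortcut for mining-layer tests (null cells
  Uniform(0,1), planted cells Uniform(0, alpha)).

One global seed is expanded into per-stage substreams, so e.g. changing the
number of voxels does not perturb the genotype draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

__all__ = [
    "EffectBlock",
    "SimConfig",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_pvalue_matrix",
    "simulate_dataset",
]

# fixed spawn keys: each generator stage gets an independent substream of the
# global seed, so resizing one stage never shifts another stage's draws
_STAGE_KEYS = {"genotypes": 0, "covariates": 1, "phenotypes": 2, "pvalues": 3}


def _stage_rng(seed: int, stage: str) -> Generator:
    return default_rng(SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],)))


def snp_id(j: int) -> str:
    return f"snp{j:04d}"


def voxel_id(v: int) -> str:
    return f"vox{v:05d}"


def subject_id(i: int) -> str:
    return f"subj{i:04d}"


@dataclass(frozen=True)
class EffectBlock:
    """A planted additive effect: each minor allele of each SNP in
    ``snp_ids`` adds ``beta`` phenotype units at every voxel in
    ``voxel_ids``.

    Indices refer to column positions of the generated matrices.
    """

    snp_ids: frozenset
    voxel_ids: frozenset
    beta: float

    def __init__(self, snp_ids, voxel_ids, beta: float):
        object.__setattr__(self, "snp_ids", frozenset(snp_ids))
        object.__setattr__(self, "voxel_ids", frozenset(voxel_ids))
        object.__setattr__(self, "beta", float(beta))
        if not self.snp_ids:
            raise ValueError("EffectBlock.snp_ids must be non-empty")
        if not self.voxel_ids:
            raise ValueError("EffectBlock.voxel_ids must be non-empty")


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset."""

    n_subjects: int
    n_snps: int
    n_voxels: int
    mafs: list = field(default_factory=list)  # per-SNP MAF in (0, 0.5]
    blocks: list = field(default_factory=list)
    noise_sd: float = 1.0
    n_covariates: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_snps <= 0 or self.n_voxels <= 0:
            raise ValueError("n_subjects, n_snps and n_voxels must be positive")
        if not self.mafs:
            self.mafs = [0.3] * self.n_snps
        if len(self.mafs) != self.n_snps:
            raise ValueError(
                f"mafs has length {len(self.mafs)}, expected n_snps={self.n_snps}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be non-negative")
        self.blocks = [
            b if isinstance(b, EffectBlock) else EffectBlock(**b) for b in self.blocks
        ]
        for b in self.blocks:
            if max(b.snp_ids) >= self.n_snps or min(b.snp_ids) < 0:
                raise ValueError("block SNP index out of range")
            if max(b.voxel_ids) >= self.n_voxels or min(b.voxel_ids) < 0:
                raise ValueError("block voxel index out of range")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_snps": self.n_snps,
            "n_voxels": self.n_voxels,
            "mafs": list(map(float, self.mafs)),
            "blocks": [
                {
                    "snp_ids": sorted(b.snp_ids),
                    "voxel_ids": sorted(b.voxel_ids),
                    "beta": b.beta,
                }
                for b in self.blocks
            ],
            "noise_sd": self.noise_sd,
            "n_covariates": self.n_covariates,
            "seed": self.seed,
        }


def _check_mafs(mafs: np.ndarray) -> None:
    bad = np.flatnonzero((mafs <= 0) | (mafs > 0.5))
    if bad.size:
        raise ValueError(
            f"MAF out of (0, 0.5] for SNP {snp_id(int(bad[0]))} "
            f"(value {mafs[bad[0]]!r})"
        )


def simulate_genotypes(n_subjects: int, mafs, seed: int = 0) -> pd.DataFrame:
    """Draw a subjects x SNPs dosage matrix in Hardy-Weinberg proportions.

    For a SNP with minor-allele frequency q, the dosage is Binomial(2, q):
    P(2) = q^2, P(1) = 2q(1-q), P(0) = (1-q)^2. SNPs are independent (no
    linkage disequilibrium).
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1:
        raise ValueError("mafs must be one-dimensional")
    _check_mafs(mafs)
    rng = _stage_rng(seed, "genotypes")
    g = rng.binomial(2, mafs, size=(n_subjects, mafs.size))
    return pd.DataFrame(
        g,
        index=[subject_id(i) for i in range(n_subjects)],
        columns=[snp_id(j) for j in range(mafs.size)],
    )


def simulate_covariates(n_subjects: int, n_covariates: int, seed: int = 0) -> pd.DataFrame:
    """Standard-normal nuisance covariates (age/education/PC stand-ins)."""
    rng = _stage_rng(seed, "covariates")
    x = rng.standard_normal((n_subjects, n_covariates))
    return pd.DataFrame(
        x,
        index=[subject_id(i) for i in range(n_subjects)],
        columns=[f"cov{k}" for k in range(n_covariates)],
    )


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    blocks,
    n_voxels: int,
    noise_sd: float = 1.0,
    covariate_betas=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Voxel phenotypes with planted additive SNP-block effects.

    y[i, v] = sum over blocks containing v of beta * (sum of the block's
    dosages for subject i) + covariate term + Normal(0, noise_sd^2) noise.
    """
    n_subjects, n_snps = genotypes.shape
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for b in blocks:
        if max(b.snp_ids) >= n_snps or min(b.snp_ids) < 0:
            raise ValueError("block SNP index out of range")
        if max(b.voxel_ids) >= n_voxels or min(b.voxel_ids) < 0:
            raise ValueError("block voxel index out of range")
    rng = _stage_rng(seed, "phenotypes")
    if noise_sd > 0:
        y = rng.normal(0.0, noise_sd, size=(n_subjects, n_voxels))
    else:
        y = np.zeros((n_subjects, n_voxels))
    g = genotypes.to_numpy(dtype=float)
    for b in blocks:
        effect = b.beta * g[:, sorted(b.snp_ids)].sum(axis=1)
        y[:, sorted(b.voxel_ids)] += effect[:, None]
    if covariates is not None and covariates.shape[1] > 0 and covariate_betas is not None:
        betas = np.asarray(covariate_betas, dtype=float)
        if betas.shape != (covariates.shape[1],):
            raise ValueError("covariate_betas length must match covariate count")
        y += (covariates.to_numpy(dtype=float) @ betas)[:, None]
    return pd.DataFrame(
        y,
        index=genotypes.index,
        columns=[voxel_id(v) for v in range(n_voxels)],
    )


def simulate_pvalue_matrix(
    n_snps: int,
    n_voxels: int,
    blocks,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Shortcut generator for the mining layer: a SNP x voxel p-value matrix.

    Cells outside all blocks are Uniform(0, 1); cells inside a block are
    Uniform(0, alpha), i.e. guaranteed sub-threshold. The mining layer only
    sees the thresholded indicator, so the exact sub-threshold shape is
    irrelevant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for b in blocks:
        if max(b.snp_ids) >= n_snps or min(b.snp_ids) < 0:
            raise ValueError("block SNP index out of range")
        if max(b.voxel_ids) >= n_voxels or min(b.voxel_ids) < 0:
            raise ValueError("block voxel index out of range")
    rng = _stage_rng(seed, "pvalues")
    p = rng.uniform(0.0, 1.0, size=(n_snps, n_voxels))
    for b in blocks:
        rows = np.asarray(sorted(b.snp_ids))
        cols = np.asarray(sorted(b.voxel_ids))
        p[np.ix_(rows, cols)] = rng.uniform(0.0, alpha, size=(rows.size, cols.size))
    return pd.DataFrame(
        p,
        index=[snp_id(j) for j in range(n_snps)],
        columns=[voxel_id(v) for v in range(n_voxels)],
    )


def simulate_dataset(config: SimConfig):
    """Generate (genotypes, covariates, phenotypes) from one SimConfig."""
    genotypes = simulate_genotypes(config.n_subjects, config.mafs, config.seed)
    covariates = simulate_covariates(config.n_subjects, config.n_covariates, config.seed)
    phenotypes = simulate_phenotypes(
        genotypes,
        covariates if config.n_covariates else None,
        config.blocks,
        config.n_voxels,
        noise_sd=config.noise_sd,
        covariate_betas=np.full(config.n_covariates, 0.5) if config.n_covariates else None,
        seed=config.seed,
    )
    return genotypes, covariates, phenotypes
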