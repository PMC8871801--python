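"""Mass-univariate voxelwise association (vGWAS) and Hardy-Weinberg QC.

For every (SNP, voxel) pair an ordinary least-squares model

    phenotype[:, v] ~ intercept + genotype[:, j] + covariates

is fitted and the two-sided p-value of the genotype coefficient's
t-statistic is recorded, giving the SNP x voxel p-value matrix that the
transactional layer thresholds.

Rather than fitting S x V separate models, phenotypes and genotypes are
each residualized once against [intercept, covariates]; by the
Frisch-Waugh-Lovell theorem the simple regression of the residualized
phenotype on the residualized genotype (with degrees of freedom
n - n_covariates - 2) yields the identical t-statistic and p-value for the
genotype coefficient. This turns the whole scan into a handful of matrix
products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VoxelGWAS",
    "VoxelGWASResults",
    "HweResult",
    "hwe_test",
    "hwe_filter",
    "run_vgwas",
]


@dataclass(frozen=True)
class HweResult:
    """Chi-square goodness-of-fit of observed genotype counts against the
    Hardy-Weinberg expectation from the sample allele frequency (1 df)."""

    snp_id: str
    n0: int
    n1: int
    n2: int
    chi2: float
    p_hw: float

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2


def hwe_test(n0: int, n1: int, n2: int, snp: str = "") -> HweResult:
    """Hardy-Weinberg chi-square test from genotype counts (0/1/2 minor
    alleles). Monomorphic SNPs fit HWE exactly (chi2 = 0, p = 1)."""
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError(f"SNP {snp or '<unnamed>'} has no observed genotypes")
    q = (2 * n2 + n1) / (2 * n)  # sample minor-allele frequency
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    observed = np.array([n0, n1, n2], dtype=float)
    mask = expected > 0
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    p_hw = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id=snp, n0=n0, n1=n1, n2=n2, chi2=chi2, p_hw=p_hw)


def hwe_filter(genotypes: pd.DataFrame, threshold: float = 1e-6):
    """Keep SNPs whose HWE p-value is >= threshold (default 1e-6).

    Returns (kept SNP ids, list of HweResult for every SNP).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    results = []
    kept = []
    for snp in genotypes.columns:
        col = genotypes[snp].to_numpy()
        if np.isnan(col.astype(float)).all():
            raise ValueError(f"SNP {snp} is entirely missing")
        res = hwe_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()), snp=snp
        )
        results.append(res)
        if res.p_hw >= threshold:
            kept.append(snp)
    return kept, results


def _align(phenotypes, genotypes, covariates):
    idx = phenotypes.index
    if not genotypes.index.equals(idx):
        if set(genotypes.index) != set(idx):
            raise ValueError("genotype and phenotype subject ids differ")
        genotypes = genotypes.loc[idx]
    if covariates is not None:
        if not covariates.index.equals(idx):
            if set(covariates.index) != set(idx):
                raise ValueError("covariate and phenotype subject ids differ")
            covariates = covariates.loc[idx]
    return genotypes, covariates


class VoxelGWAS:
    """Mass-univariate linear model of voxel phenotypes on SNP dosages.

    Parameters
    ----------
    phenotypes : DataFrame, subjects x voxels
    genotypes : DataFrame, subjects x SNPs, additive dosages in {0, 1, 2}
    covariates : DataFrame, subjects x covariates, optional
        Nuisance regressors (sex, age, education, genotype PCs, ...)
        included in every per-pair model.
    """

    def __init__(self, phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
                 covariates: pd.DataFrame | None = None):
        genotypes, covariates = _align(phenotypes, genotypes, covariates)
        self.phenotypes = phenotypes
        self.genotypes = genotypes
        self.covariates = covariates
        n = phenotypes.shape[0]
        ncov = 0 if covariates is None else covariates.shape[1]
        x = np.ones((n, 1 + ncov))
        if ncov:
            x[:, 1:] = covariates.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("covariate matrix (with intercept) is rank deficient")
        self._x = x
        self.df_resid = n - ncov - 2
        if self.df_resid <= 0:
            raise ValueError("not enough subjects for the requested model")

    @classmethod
    def from_tsv(cls, phenotype_path, genotype_path, covariate_path=None):
        from .io import read_matrix_tsv

        covariates = read_matrix_tsv(covariate_path) if covariate_path else None
        return cls(read_matrix_tsv(phenotype_path), read_matrix_tsv(genotype_path),
                   covariates)

    def fit(self) -> "VoxelGWASResults":
        q, _ = np.linalg.qr(self._x)
        y = self.phenotypes.to_numpy(dtype=float)
        g = self.genotypes.to_numpy(dtype=float)
        yr = y - q @ (q.T @ y)
        gr = g - q @ (q.T @ g)
        gnorm = np.linalg.norm(gr, axis=0)
        ynorm = np.linalg.norm(yr, axis=0)
        mono = gnorm <= 1e-12 * max(1.0, float(np.abs(g).max(initial=0.0)))
        if mono.any():
            bad = list(self.genotypes.columns[mono])
            warnings.warn(
                f"{len(bad)} SNP(s) have zero genotype variance after covariate "
                f"adjustment (e.g. {bad[0]}); their p-values are set to 1",
                stacklevel=2,
            )
        gsafe = np.where(mono, 1.0, gnorm)
        ysafe = np.where(ynorm <= 0, 1.0, ynorm)
        cross = gr.T @ yr  # S x V
        r = cross / np.outer(gsafe, ysafe)
        np.clip(r, -1.0, 1.0, out=r)
        df = self.df_resid
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
        betas = cross / np.where(mono, 1.0, gnorm**2)[:, None]
        pvals[mono, :] = 1.0
        t[mono, :] = 0.0
        betas[mono, :] = 0.0
        # constant phenotype columns carry no evidence either
        flaty = ynorm <= 0
        if flaty.any():
            pvals[:, flaty] = 1.0
            t[:, flaty] = 0.0
        snps, voxels = self.genotypes.columns, self.phenotypes.columns
        return VoxelGWASResults(
            model=self,
            pvalues=pd.DataFrame(pvals, index=snps, columns=voxels),
            tvalues=pd.DataFrame(t, index=snps, columns=voxels),
            params=pd.DataFrame(betas, index=snps, columns=voxels),
            df_resid=df,
            monomorphic=list(self.genotypes.columns[mono]),
        )


@dataclass
class VoxelGWASResults:
    """Per-pair genotype-coefficient estimates, t-statistics and p-values."""

    model: VoxelGWAS
    pvalues: pd.DataFrame
    tvalues: pd.DataFrame
    params: pd.DataFrame
    df_resid: int
    monomorphic: list

    def summary(self, alpha: float = 0.05) -> str:
        p = self.pvalues.to_numpy()
        lines = [
            "Voxelwise GWAS (per-pair OLS, additive dosage coding)",
            f"  subjects:            {self.model.phenotypes.shape[0]}",
            f"  SNPs x voxels:       {p.shape[0]} x {p.shape[1]}",
            f"  residual df:         {self.df_resid}",
            f"  monomorphic SNPs:    {len(self.monomorphic)}",
            f"  min p-value:         {p.min():.3g}",
            f"  frac p <= {alpha:g}:      {(p <= alpha).mean():.4f}",
        ]
        return "\n".join(lines)


def run_vgwas(genotypes: pd.DataFrame, phenotypes: pd.DataFrame,
              covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Convenience wrapper: fit the mass-univariate model and return the
    SNP x voxel p-value matrix."""
    return VoxelGWAS(phenotypes, genotypes, covariates).fit().pvalues
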