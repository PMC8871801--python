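# snpfim

Frequent-itemset mining of voxelwise GWAS results: finding groups of SNPs
that are jointly significant across many brain voxels.

## The problem

A voxel-based genome-wide association study (vGWAS) tests every SNP against
every voxel of an imaging phenotype (e.g. gray-matter density), yielding a
SNP × voxel matrix of p-values. Single-marker scans of this matrix miss
*sets* of SNPs that act together on the same brain regions. `snpfim` treats
the matrix as a market-basket problem:

* each **voxel** is a *transaction*;
* a SNP l_i is an **item** of that transaction iff its association p-value
  at the voxel satisfies P(l_i) ≤ α (default α = 0.05);
* the **support** of an itemset is the number of transactions containing
  all of its items, and the **support rate** is
  Support_rate = Support / TD_num, with TD_num the total transaction count;
* a **frequent itemset (FI)** is any SNP set with support rate ≥ a
  threshold *s* — a group of SNPs co-significant over at least that
  fraction of the voxels;
* an **association rule** A → B between disjoint parts of an FI is scored
  by its confidence, Confidence(A→B) = Support(A ∪ B) / Support(A), the
  conditional frequency of B among the voxels where A occurs.

Frequent itemsets are mined with either **FP-Growth** (compressed prefix
tree with per-item pointer chains and recursive conditional trees) or
**Eclat** (vertical transaction-id sets with recursive intersection); a
brute-force level-wise Apriori serves as an independent oracle in the test
suite — all three provably return identical (itemset, support) sets.
Finally, a frequent SNP is said to **activate** an anatomical ROI when the
top 20% of the ROI's voxels, ranked by association strength for that SNP,
are all significant.

Upstream, the package provides the vGWAS itself (per-pair OLS with
covariates, computed via one-shot covariate residualization — the
Frisch-Waugh-Lovell theorem makes it exactly equivalent to the full model),
a Hardy-Weinberg equilibrium chi-square filter (keep p_HW ≥ 10⁻⁶), and a
synthetic-data generator that plants multi-SNP / multi-voxel additive
effects so the whole pipeline is testable without access-restricted
genotype/MRI data.

## Worked example

```python
import snpfim as sf

# plant a 3-SNP effect on the first 40 voxels of a 60-voxel "ROI"
block = sf.EffectBlock(snp_ids=[0, 1, 2], voxel_ids=range(40), beta=1.0)
geno = sf.simulate_genotypes(300, [0.3] * 8, seed=11)
cov = sf.simulate_covariates(300, 2, seed=11)
phen = sf.simulate_phenotypes(geno, cov, [block], n_voxels=60,
                              noise_sd=1.0, covariate_betas=[0.5, -0.5], seed=11)

model = sf.VoxelGWAS(phen, geno, cov)
results = model.fit()
print(results.summary())

td = sf.build_transactions(results.pvalues, alpha=0.05)
print(f"\nTD_num = {td.td_num}, items = {len(td.items)}")

mined = sf.eclat(td, s=0.5)
print(f"FIs at s=0.5: {sf.count_by_size(mined)}")
best = mined.top(k=3, n=1)[0]
print(f"top 3-item FI: {best.items}  support_rate = {best.support_rate:.3f}")

for rule in sf.rule_chain(best.items, td):
    print(rule)
```

prints

```
Voxelwise GWAS (per-pair OLS, additive dosage coding)
  subjects:            300
  SNPs x voxels:       8 x 60
  residual df:         296
  monomorphic SNPs:    0
  min p-value:         9.85e-23
  frac p <= 0.05:      0.2875

TD_num = 60, items = 8
FIs at s=0.5: {1: 3, 2: 3, 3: 1}
top 3-item FI: ('snp0000', 'snp0001', 'snp0002')  support_rate = 0.667
snp0000 -> snp0001 [conf 1.00]
snp0000, snp0001 -> snp0002 [conf 1.00]
```

The three planted SNPs — and only they — form a frequent 3-itemset: they
are jointly significant on 0.667 of the voxels (the planted 40/60 fraction,
since every planted cell reaches p ≤ 0.05 at this effect size), and the
prefix rule chain shows each of them is always accompanied by the others
(confidence 1.00). The five null SNPs are significant on only ~5% of voxels
and never reach the s = 0.5 threshold.

The same pipeline runs from the shell:

```bash
snpfim run --config config.yaml        # simulate/load → vGWAS → TD → mine → rules → activation
snpfim mine --algo eclat --min-support 0.5 --input td.basket --out fi.tsv
snpfim sweep --input td.basket --s-grid 0.3,0.5,0.7 --out sweep.tsv
```

All matrices travel as TSV, transactions as FIMI basket files (one
whitespace-separated line per transaction), and each full run writes a
`manifest.json` echoing every parameter and seed.

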