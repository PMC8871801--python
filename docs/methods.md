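# Methods

## Pipeline model

The framework converts a mass-univariate imaging-genetics scan into a
market-basket analysis and back into anatomical statements:

1. **vGWAS.** For every SNP j and voxel v, ordinary least squares of the
   voxel phenotype on [intercept, dosage_j, covariates]; the entry of the
   p-value matrix is the two-sided p-value of the genotype coefficient's
   t-statistic with n − (n_covariates + 2) residual degrees of freedom.
   Two-sidedness is assumed (the convention of standard GWAS tooling).
   Genotypes are additively coded dosages in {0, 1, 2}; missing genotypes
   are unsupported and must be pre-imputed. SNPs failing a Hardy-Weinberg
   chi-square test (p_HW < 10⁻⁶, 1 df, expectation from the sample allele
   frequency) are removed first. The chi-square form was chosen over the
   exact test because sample sizes in the hundreds-to-thousands make the
   asymptotic a non-issue; the function boundary makes it swappable.

2. **Transactionalization.** Voxel v's transaction contains SNP l_i iff
   P(l_i) ≤ α, with α = 0.05 by default and the comparison deliberately
   inclusive (≤, documented to avoid </≤ drift). No multiple-testing
   correction is applied by default: the subsequent frequency-of-occurrence
   filtering is itself the guard against isolated false positives. A
   Benjamini-Hochberg switch exists (`fdr=True`) but defaults off. Empty
   transactions are retained so support rates keep the full-ROI
   denominator TD_num.

3. **Mining.** An itemset is frequent iff support / TD_num ≥ s. The
   comparison is evaluated in exact rational arithmetic
   (`fractions.Fraction`), never floating point, so an itemset sitting
   exactly on the threshold (3/5 at s = 0.6) is kept deterministically.
   FP-Growth inserts items in descending-support order with lexicographic
   tie-break (required for reproducible trees), threads per-item pointer
   chains, and recurses over conditional pattern bases, with the
   single-path shortcut enumerating path subsets directly. Eclat stores
   plain sorted tidsets and intersects them class by class; the diffset
   optimization is deliberately omitted. Both use explicit work stacks
   rather than Python recursion, since item universes of ~2000 SNPs can
   exceed default recursion depth. A naive level-wise Apriori (candidate
   join + subset pruning + full scans) is kept in the package purely as the
   independent oracle; equivalence of all three on randomized databases is
   asserted in the test suite. Output ordering is (k, descending support
   rate, lexicographic items) so "top 5" tables are deterministic.

4. **Rules.** Confidence(A→B) = Support(A ∪ B) / Support(A), computed on
   integer counts recomputed from the transaction DB, hence exact. The
   "support of A and B" is the support of the union itemset — the standard
   association-rule reading. Default rule policy: for each frequent
   itemset, every single-item-consequent split (for pairs this is both
   directions; for larger sets the (k−1)→1 rules); a full power-set policy
   exists behind a flag but is exponential and non-default. Rules below
   the confidence floor (default 0.8, the conventional "relatively high"
   working threshold) are flagged, never silently dropped, and report
   tables print them as `--`. Display rounding is half-up to 2 decimals;
   internal values are never rounded.

5. **Activation.** An ROI is activated by a SNP when the top
   ceil(top_frac · |ROI|) of its voxels — ranked descending by
   −log₁₀(p) for that SNP, ties broken by voxel identifier — are all
   significant (p ≤ α; defaults top_frac = 0.2, α = 0.05, the strict `<`
   variant is configurable). Ranking by per-voxel association strength is
   a design decision worth flagging: "heritability" rankings in the
   literature leave the estimator unspecified, and association strength is
   the only per-voxel SNP-specific quantity this pipeline possesses. The
   ceiling keeps at least one voxel in tiny ROIs.

## Computational notes

The vGWAS is computed by residualizing the phenotype matrix and the
genotype matrix once against [intercept, covariates] (QR projection) and
then forming all S × V correlation-based t-tests as three matrix products.
By Frisch-Waugh-Lovell this equals the full per-pair model exactly (the
test suite verifies agreement with independently fitted OLS to 1e-10); it
makes the 1784-SNP × 49,900-voxel scale of a real study feasible and
desk-scale instant. Zero-variance (monomorphic) SNPs get p = 1 with a
warning — they carry no association evidence; rank-deficient covariates
are rejected outright. Adding a covariate orthogonal to both genotype and
phenotype leaves the partial correlation exactly invariant; the p-value
moves only through the one-degree-of-freedom change in the reference
distribution, which is how the corresponding test asserts it.

## Synthetic data

The generator emulates the *joint structure* the pipeline needs, not MRI
realism:

* **Genotypes**: dosage ~ Binomial(2, q) per SNP, i.e. exact Hardy-Weinberg
  proportions at the chosen MAF; SNPs i.i.d. (no linkage disequilibrium —
  LD-aware simulation is a non-goal here).
* **Phenotypes**: y[i, v] = Σ_blocks β · (block dosage sum) + covariate
  term + N(0, σ²) noise. A planted `EffectBlock` makes its SNP set
  co-significant over its voxel set, which is exactly the signal the miner
  must recover. Default β is a free parameter; 1.0 phenotype-SD units per
  minor allele at n = 500 gives per-cell power > 0.99 at α = 0.05 (a
  noncentrality of ≈ 9 with five-SNP background variation included) and is
  what the end-to-end recovery tests use.
* **P-value shortcut**: null cells Uniform(0, 1), planted cells
  Uniform(0, α). Planted cells are not drawn from a noncentral
  distribution on purpose — the mining layer only sees the thresholded
  indicator, so the simplest guaranteed-sub-threshold shape suffices.
* **Seeding**: one global seed expanded into fixed per-stage substreams
  (`SeedSequence(seed, spawn_key=(stage,))`), so changing the voxel count
  cannot perturb genotype draws; every generator is bit-reproducible.

What passing tests do *not* show about real data: no spatial smoothness of
voxel noise, no LD between SNPs, no population stratification, and no MRI
preprocessing chain — planted-recovery results quantify the pipeline's
behaviour under its own model, not imaging reality.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | per-cell significance for item membership |
| s | caller-set, grid [0.3, 0.5, 0.7] in the driver | minimum support rate |
| min_confidence | 0.8 | rule-report floor (flagging, not filtering) |
| top_frac | 0.2 | activated-ROI voxel fraction |
| p_HW threshold | 10⁻⁶ | HWE QC filter |
| planted-recovery conditions | n = 500 subjects, 10 SNPs, 300 voxels, one 5-SNP block on 70% of voxels, β = 1.0, σ = 1 | end-to-end study conditions |

Property tests run on randomized databases of ≤ 15 items × ≤ 60
transactions (the scale at which the Apriori oracle is instant); the
equivalence suite uses 100 such databases. These sizes were chosen so the
whole suite runs in seconds while still exercising deep conditional trees
and multi-level recursion.

## Known limitations

* Missing genotypes and non-additive codings are unsupported.
* No closed/maximal itemset mining and no lift/leverage/conviction rule
  metrics.
* ROI maps are abstract voxel→label tables; no NIfTI/atlas I/O.
* The Apriori oracle is intentionally slow and guards (with a warning)
  above ~25 distinct items.
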