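"""Mass-univariate association scan and Hardy-Weinberg QC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from snpfim import VoxelGWAS, hwe_filter, hwe_test, run_vgwas, simulate_genotypes


def _frame(arr, prefix):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestVoxelGWAS:
    def test_matches_simple_regression_closed_form(self):
        rng = np.random.default_rng(0)
        n = 80
        g = _frame(rng.binomial(2, 0.3, (n, 1)), "s")
        y = _frame(0.3 * g.to_numpy() + rng.standard_normal((n, 1)), "v")
        p = run_vgwas(g, y).iloc[0, 0]
        ref = stats.linregress(g.iloc[:, 0], y.iloc[:, 0]).pvalue
        assert abs(p - ref) < 1e-10

    def test_matches_full_ols_with_covariates(self):
        rng = np.random.default_rng(1)
        n = 120
        g = _frame(rng.binomial(2, 0.25, (n, 4)), "s")
        x = _frame(rng.standard_normal((n, 3)), "c")
        y = _frame(rng.standard_normal((n, 5)) + 0.2 * g.iloc[:, [0]].to_numpy(), "v")
        ours = run_vgwas(g, y, x)
        for snp in g.columns:
            for vox in y.columns:
                design = sm.add_constant(
                    np.column_stack([g[snp].to_numpy(dtype=float), x.to_numpy()])
                )
                ref = sm.OLS(y[vox].to_numpy(), design).fit().pvalues[1]
                assert abs(ours.loc[snp, vox] - ref) < 1e-10

    def test_perfect_fit_gives_numerically_zero_p(self):
        g = _frame(np.repeat([0, 1, 2], 10).reshape(-1, 1), "s")
        y = _frame(g.to_numpy(dtype=float), "v")
        assert run_vgwas(g, y).iloc[0, 0] < 1e-12

    def test_null_pvalues_uniform_fraction(self):
        rng = np.random.default_rng(2)
        n = 200
        g = _frame(rng.binomial(2, 0.3, (n, 50)), "s")
        y = _frame(rng.standard_normal((n, 200)), "v")
        frac = (run_vgwas(g, y).to_numpy() <= 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / (50 * 200))
        assert abs(frac - 0.05) < 3 * sd

    def test_monomorphic_snp_warns_and_scores_one(self):
        g = _frame(np.column_stack([np.ones(30), np.tile([0, 1, 2], 10)]), "s")
        y = _frame(np.random.default_rng(3).standard_normal((30, 2)), "v")
        with pytest.warns(UserWarning, match="zero genotype variance"):
            p = run_vgwas(g, y)
        assert (p.loc["s0"] == 1.0).all()
        assert (p.loc["s1"] < 1.0).any()

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(4)
        g = _frame(rng.binomial(2, 0.3, (40, 2)), "s")
        y = _frame(rng.standard_normal((40, 2)), "v")
        x = _frame(np.ones((40, 1)), "c")  # collinear with the intercept
        with pytest.raises(ValueError, match="rank deficient"):
            VoxelGWAS(y, g, x)

    def test_invariant_to_subject_permutation(self):
        rng = np.random.default_rng(5)
        n = 60
        g = _frame(rng.binomial(2, 0.4, (n, 3)), "s")
        x = _frame(rng.standard_normal((n, 2)), "c")
        y = _frame(rng.standard_normal((n, 4)), "v")
        ids = [f"sub{i}" for i in range(n)]
        for df in (g, x, y):
            df.index = ids
        base = run_vgwas(g, y, x)
        perm = rng.permutation(n)
        shuffled = run_vgwas(g.iloc[perm], y.iloc[perm], x.iloc[perm])
        np.testing.assert_allclose(base.to_numpy(), shuffled.to_numpy(), atol=1e-10)

    def test_orthogonal_covariate_leaves_p_unchanged(self):
        rng = np.random.default_rng(6)
        n = 100
        g = _frame(rng.binomial(2, 0.3, (n, 1)), "s")
        y = _frame(rng.standard_normal((n, 1)), "v")
        z = rng.standard_normal(n)
        basis = np.column_stack([np.ones(n), g.to_numpy(), y.to_numpy()])
        q, _ = np.linalg.qr(basis)
        z -= q @ (q.T @ z)  # orthogonal to intercept, genotype and phenotype
        p0 = run_vgwas(g, y).iloc[0, 0]
        p1 = run_vgwas(g, y, _frame(z.reshape(-1, 1), "c")).iloc[0, 0]
        # the partial correlation is exactly invariant; the p-value moves
        # only through the one-df change in the reference distribution
        t0 = stats.t.isf(p0 / 2, n - 2)
        t1 = stats.t.isf(p1 / 2, n - 3)
        r0 = t0 / np.sqrt(t0**2 + n - 2)
        r1 = t1 / np.sqrt(t1**2 + n - 3)
        assert abs(r0 - r1) < 1e-10
        assert abs(p0 - p1) < 5e-3

    def test_misaligned_subjects_rejected(self):
        rng = np.random.default_rng(7)
        g = _frame(rng.binomial(2, 0.3, (10, 1)), "s")
        y = _frame(rng.standard_normal((10, 1)), "v")
        g.index = [f"a{i}" for i in range(10)]
        y.index = [f"b{i}" for i in range(10)]
        with pytest.raises(ValueError, match="subject ids"):
            run_vgwas(g, y)

    def test_results_summary_mentions_shape(self):
        rng = np.random.default_rng(8)
        g = _frame(rng.binomial(2, 0.3, (30, 2)), "s")
        y = _frame(rng.standard_normal((30, 3)), "v")
        text = VoxelGWAS(y, g).fit().summary()
        assert "2 x 3" in text and "residual df" in text


class TestHWE:
    def test_exact_proportions_score_chi2_zero(self):
        res = hwe_test(25, 50, 25, snp="rs1")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_hw == pytest.approx(1.0)
        assert res.n == 100

    def test_missing_heterozygotes_fail_hard(self):
        # (50, 0, 50) at q = 0.5: expected (25, 50, 25), chi2 = 25+50+25 = 100
        res = hwe_test(50, 0, 50)
        assert res.chi2 == pytest.approx(100.0)
        assert res.p_hw < 1e-6

    def test_monomorphic_counts_fit_exactly(self):
        res = hwe_test(40, 0, 0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_filter_keeps_hwe_simulated_snps(self):
        g = simulate_genotypes(200, [0.3] * 1000, seed=13)
        kept, results = hwe_filter(g, threshold=1e-6)
        assert len(results) == 1000
        assert len(kept) >= 999  # type-I error is ~1e-6 per SNP

    def test_filter_removes_gross_violations(self):
        g = pd.DataFrame({"bad": [0] * 50 + [2] * 50, "good": [0, 1, 2] * 33 + [1]})
        kept, _ = hwe_filter(g)
        assert kept == ["good"]

    def test_threshold_range_checked(self):
        g = pd.DataFrame({"s": [0, 1, 2, 1]})
        with pytest.raises(ValueError):
            hwe_filter(g, threshold=2.0)
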