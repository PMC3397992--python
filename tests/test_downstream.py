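"""Differential expression, effect sizes, permutation null, and QTL mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endopheno.downstream import (
    cohens_d,
    differential_expression,
    mgl_qtl,
    permutation_validation,
    u_allele_frequencies,
)


def make_groups(shift=0.0, m=50, n1=30, n2=40, seed=0):
    rng = np.random.default_rng(seed)
    case = rng.normal(shift, 1.0, (m, n1))
    control = rng.normal(0.0, 1.0, (m, n2))
    return pd.DataFrame(case), pd.DataFrame(control)


class TestDifferentialExpression:
    def test_identical_groups_not_significant(self):
        X = pd.DataFrame(np.tile([1.0, 2.0, 3.0, 4.0], (5, 1)))
        out = differential_expression(X, X.copy(), alpha=1e-4)
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p"], 1.0)
        assert not out["significant"].any()

    def test_one_sd_shift_detected_at_strict_alpha(self):
        """Shift of 1 pooled SD at n = 80 vs 188 gives power > 0.99 at 1e-4."""
        rng = np.random.default_rng(1)
        m = 200
        case = pd.DataFrame(rng.normal(1.0, 1.0, (m, 80)))
        control = pd.DataFrame(rng.normal(0.0, 1.0, (m, 188)))
        out = differential_expression(case, control, alpha=1e-4)
        assert out["significant"].mean() > 0.97

    def test_type_I_rate_matches_alpha_under_null(self):
        """Null DE significant count within binomial 99% bounds of alpha*m."""
        case, control = make_groups(0.0, m=4000, seed=2)
        out = differential_expression(case, control, alpha=0.05)
        count = int(out["significant"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 4000, 0.05)
        assert lo <= count <= hi

    def test_t_and_d_algebraic_relation(self):
        """Pooled-variance t equals d * sqrt(n1 n2 / (n1 + n2))."""
        case, control = make_groups(0.3, seed=3)
        out = differential_expression(case, control)
        n1, n2 = case.shape[1], control.shape[1]
        expected_t = out["cohens_d"] * np.sqrt(n1 * n2 / (n1 + n2))
        assert np.allclose(out["t"], expected_t, rtol=1e-10)

    def test_welch_option_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(4)
        case = pd.DataFrame(rng.normal(0, 3.0, (20, 10)))
        control = pd.DataFrame(rng.normal(0, 0.5, (20, 50)))
        pooled = differential_expression(case, control)
        welch = differential_expression(case, control, equal_var=False)
        assert not np.allclose(pooled["p"], welch["p"])


class TestCohensD:
    def test_known_values(self):
        case = pd.DataFrame([[0.0, 2.0]])      # mean 1, sd sqrt(2)
        control = pd.DataFrame([[-1.0, 1.0]])  # mean 0, sd sqrt(2)
        d = cohens_d(case, control)
        assert d[0] == pytest.approx(1.0 / np.sqrt(2))

    def test_equal_means_zero(self):
        X = pd.DataFrame(np.random.default_rng(5).random((10, 6)))
        assert np.allclose(cohens_d(X, X.copy()), 0.0)

    def test_shift_invariance(self):
        case, control = make_groups(0.4, seed=6)
        base = cohens_d(case, control)
        shifted = cohens_d(case + 11.3, control + 11.3)
        assert np.allclose(base, shifted, rtol=1e-10)


class TestPermutationValidation:
    def test_null_quantiles_match_brute_force_oracle(self):
        """Quantile-averaged null curves equal a direct reimplementation."""
        case, control = make_groups(0.5, m=120, n1=30, n2=40, seed=7)
        sizes = [10, 10, 10]
        n_q = 99
        result = permutation_validation(case, control, sizes, n_perm=12,
                                        seed=0, n_quantiles=n_q)
        # independent re-computation: same RNG protocol, scipy quantiles
        rng = np.random.default_rng(0)
        grid = np.arange(1, n_q + 1) / (n_q + 1)
        X, Y = case.to_numpy(), control.to_numpy()
        acc = np.zeros((3, n_q))
        for _ in range(12):
            perm = rng.permutation(30)
            start = 0
            for s, size in enumerate(sizes):
                cols = perm[start:start + size]
                start += size
                sub = X[:, cols]
                n1, n2 = size, 40
                pooled = np.sqrt(((n1 - 1) * sub.var(1, ddof=1)
                                  + (n2 - 1) * Y.var(1, ddof=1)) / (n1 + n2 - 2))
                d = (sub.mean(1) - Y.mean(1)) / pooled
                acc[s] += np.quantile(d, grid)
        assert np.allclose(result.null_quantiles.to_numpy(), (acc / 12).T)

    def test_null_centered_like_all_cases(self):
        """Random regroupings keep the location of the pooled-cases curve."""
        case, control = make_groups(0.5, m=300, n1=60, n2=80, seed=7)
        result = permutation_validation(case, control, [20, 20, 20],
                                        n_perm=30, seed=0, n_quantiles=199)
        all_median = np.median(result.all_cases_quantiles)
        for col in result.null_quantiles:
            assert np.median(result.null_quantiles[col]) == pytest.approx(
                all_median, abs=0.1)

    def test_observed_planted_subtypes_wider_than_null(self):
        """Real structured subtypes spread effect sizes beyond permutations."""
        rng = np.random.default_rng(8)
        m, per = 300, 25
        control = pd.DataFrame(rng.normal(0, 1, (m, 60)))
        blocks = []
        for s in range(3):
            block = rng.normal(0, 1, (m, per))
            block[s * 100:(s + 1) * 100] += 1.5  # subtype-specific DE genes
            blocks.append(block)
        case = pd.DataFrame(np.hstack(blocks))
        labels = np.repeat([1, 2, 3], per)
        result = permutation_validation(case, control, [per] * 3, n_perm=30,
                                        seed=1, observed_labels=labels,
                                        n_quantiles=199)
        null_iqr = np.subtract(*np.percentile(result.null_quantiles.iloc[:, 0], [75, 25]))
        obs_iqr = np.subtract(*np.percentile(result.observed_quantiles.iloc[:, 0], [75, 25]))
        assert obs_iqr > null_iqr * 1.2

    def test_deterministic_under_seed(self):
        case, control = make_groups(0.2, m=40, n1=12, n2=15, seed=9)
        a = permutation_validation(case, control, [6, 6], n_perm=2, seed=3,
                                   n_quantiles=99)
        b = permutation_validation(case, control, [6, 6], n_perm=2, seed=3,
                                   n_quantiles=99)
        assert a.null_quantiles.equals(b.null_quantiles)

    def test_bad_sizes_rejected(self):
        case, control = make_groups(0.0, m=10, n1=10, n2=10)
        with pytest.raises(ValueError):
            permutation_validation(case, control, [4, 4], n_perm=5)
        with pytest.raises(ValueError):
            permutation_validation(case, control, [5, 5], n_perm=1)


def hwe_genotypes(rng, p, n):
    return rng.binomial(2, p, size=n)


class TestMglQtl:
    def test_parameter_recovery(self):
        """MGL = 2 + 0.5 G + N(0, 0.1) at n = 176 recovers the slope."""
        rng = np.random.default_rng(10)
        n = 176
        G = np.vstack([hwe_genotypes(rng, 0.3, n) for _ in range(30)])
        geno = pd.DataFrame(G, index=[f"snp{i}" for i in range(30)])
        y = 2.0 + 0.5 * G[0] + rng.normal(0, 0.1, n)
        out = mgl_qtl(y, geno, alpha=1e-4)
        assert out.loc["snp0", "slope"] == pytest.approx(0.5, abs=0.02)
        assert out.loc["snp0", "significant"]
        assert out.loc["snp0", "u_allele"] == "minor"

    def test_slope_agrees_with_statsmodels(self):
        """Cross-check slope/p against an independent OLS implementation."""
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        n = 60
        G = np.vstack([hwe_genotypes(rng, 0.4, n) for _ in range(5)])
        geno = pd.DataFrame(G, index=[f"snp{i}" for i in range(5)])
        y = 1.0 + 0.3 * G[2] + rng.normal(0, 0.5, n)
        out = mgl_qtl(y, geno, alpha=0.01)
        for i in range(5):
            fit = sm.OLS(y, sm.add_constant(G[i].astype(float))).fit()
            assert out.iloc[i]["slope"] == pytest.approx(fit.params[1], rel=1e-9)
            assert out.iloc[i]["p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_null_significant_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        n, n_snps = 100, 2000
        G = np.vstack([hwe_genotypes(rng, 0.3, n) for _ in range(n_snps)])
        geno = pd.DataFrame(G, index=[f"snp{i}" for i in range(n_snps)])
        y = rng.normal(0, 1, n)
        out = mgl_qtl(y, geno, alpha=0.05)
        lo, hi = stats.binom.ppf([0.005, 0.995], n_snps, 0.05)
        assert lo <= int(out["significant"].sum()) <= hi

    def test_coding_reversal_flips_slope_and_u_allele(self):
        rng = np.random.default_rng(13)
        n = 80
        G = np.vstack([hwe_genotypes(rng, 0.3, n) for _ in range(4)])
        geno = pd.DataFrame(G, index=[f"snp{i}" for i in range(4)])
        y = 0.4 * G[1] + rng.normal(0, 0.3, n)
        fwd = mgl_qtl(y, geno)
        rev = mgl_qtl(y, 2 - geno)
        assert np.allclose(fwd["slope"], -rev["slope"])
        flips = {"minor": "major", "major": "minor"}
        assert [flips[u] for u in fwd["u_allele"]] == list(rev["u_allele"])

    def test_constant_snp_skipped(self):
        geno = pd.DataFrame([[1, 1, 1, 1], [0, 1, 2, 1]],
                            index=["flat", "ok"])
        with pytest.warns(UserWarning):
            out = mgl_qtl(np.array([0.1, 0.4, 0.9, 0.5]), geno)
        assert out.loc["flat", "u_allele"] == "undefined"
        assert not out.loc["flat", "significant"]


class TestUAlleleFrequencies:
    def test_all_heterozygous_gives_half(self):
        geno = pd.DataFrame([[1, 1, 1, 1]], index=["snp0"])
        qtl = pd.DataFrame({"slope": [0.5], "significant": [True],
                            "u_allele": ["minor"]}, index=["snp0"])
        out = u_allele_frequencies({"MGL1": qtl}, geno, [1, 1, 1, 1])
        assert out.loc[0, "mean_u_freq"] == 0.5

    def test_major_u_allele_complement(self):
        geno = pd.DataFrame([[0, 0, 2, 2]], index=["snp0"])
        qtl = pd.DataFrame({"slope": [-0.5], "significant": [True],
                            "u_allele": ["major"]}, index=["snp0"])
        out = u_allele_frequencies({"MGL1": qtl}, geno, [1, 1, 2, 2])
        # subtype 1: minor freq 0 -> major 1; subtype 2: minor 1 -> major 0
        by = out.set_index("subtype")["mean_u_freq"]
        assert by[1] == 1.0 and by[2] == 0.0

    def test_planted_subtype_has_highest_u_frequency(self, small_dataset):
        """Each subtype is enriched for the u-alleles of its own MGL-QTL."""
        from endopheno.nmf import KLNMF
        from endopheno.selection import match_labels
        expr, geno, truth = small_dataset
        fit = KLNMF(expr, 3).fit(seed=0, max_iter=500, tol=1e-6)
        labels = match_labels(fit.assign_clusters(), truth.subtype_labels)
        tables = {}
        for a in range(3):
            # align metagene a with the subtype its H row peaks in
            sub = int(np.argmax([fit.H[a][truth.subtype_labels == s + 1].mean()
                                 for s in range(3)])) + 1
            tables[f"subtype{sub}"] = mgl_qtl(fit.H[a], geno, alpha=1e-4)
        summary = u_allele_frequencies(tables, geno, truth.subtype_labels)
        for name, group in summary.groupby("mgl"):
            own = int(name.replace("subtype", ""))
            by = group.set_index("subtype")["mean_u_freq"]
            assert by.idxmax() == own
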