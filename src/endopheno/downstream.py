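"""Subtype-level downstream analyses.

Differential expression of cases (or one molecular subtype) against
controls by per-transcript t-tests, Cohen's d effect sizes, a permutation
check that the subtypes sharpen effect sizes beyond random regroupings, and
metagene-expression QTL mapping: each metagene expression level (MGL, one
row of H) regressed on each SNP's additive dosage, with the "u-allele"
defined as the allele whose dosage carries a positive slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "differential_expression",
    "cohens_d",
    "permutation_validation",
    "PermutationValidationResult",
    "mgl_qtl",
    "u_allele_frequencies",
]


def _group_arrays(case, control):
    X = case.to_numpy(dtype=float) if isinstance(case, pd.DataFrame) else np.asarray(case, dtype=float)
    Y = control.to_numpy(dtype=float) if isinstance(control, pd.DataFrame) else np.asarray(control, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("case and control must cover the same transcripts")
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    return X, Y


def cohens_d(case, control) -> np.ndarray:
    """Per-transcript Cohen's d with the pooled (n1+n2-2) standard deviation.

    Zero pooled SD yields NaN (flagged undefined).
    """
    X, Y = _group_arrays(case, control)
    n1, n2 = X.shape[1], Y.shape[1]
    s1 = X.var(axis=1, ddof=1)
    s2 = Y.var(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (X.mean(axis=1) - Y.mean(axis=1)) / pooled
    return np.where(pooled > 0, d, np.nan)


def differential_expression(
    case, control, alpha: float = 1e-4, *, equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per transcript (pooled variance by default).

    Returns a table with t, p, Cohen's d and a significance flag at
    ``alpha``.  Degenerate transcripts (zero variance in both groups) get
    p = 1 when the means agree, p = 0 otherwise.
    """
    X, Y = _group_arrays(case, control)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(X, Y, axis=1, equal_var=equal_var)
    degenerate = (X.var(axis=1) == 0) & (Y.var(axis=1) == 0)
    same_mean = np.isclose(X.mean(axis=1), Y.mean(axis=1))
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate & same_mean, 1.0, p)
    p = np.where(degenerate & ~same_mean, 0.0, p)
    index = case.index if isinstance(case, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    out = pd.DataFrame({
        "t": t,
        "p": p,
        "cohens_d": cohens_d(case, control),
        "significant": p < alpha,
    }, index=index)
    return out


@dataclass
class PermutationValidationResult:
    """Quantile-combined null effect-size distributions per pseudo-subtype.

    ``null_quantiles``: per pseudo-subtype, each quantile of the Cohen's d
    distribution averaged across permutations on ``quantile_grid``.
    ``observed_quantiles`` holds the same grid for the real subtypes (if
    labels were supplied) and for the pooled all-cases comparison.
    """

    quantile_grid: np.ndarray
    null_quantiles: pd.DataFrame
    all_cases_quantiles: np.ndarray
    observed_quantiles: pd.DataFrame | None
    n_perm: int

    def ks_null_vs_all(self) -> Dict[str, float]:
        """KS distance between each combined null and the all-cases curve.

        Random regroupings should look like the pooled comparison, so these
        distances are expected to be small.
        """
        return {
            col: float(np.max(np.abs(
                np.sort(self.null_quantiles[col].to_numpy())
                - np.sort(self.all_cases_quantiles))))
            for col in self.null_quantiles.columns
        }


def permutation_validation(
    case_expr,
    control_expr,
    subtype_sizes: Sequence[int],
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    observed_labels=None,
    n_quantiles: int = 999,
) -> PermutationValidationResult:
    """Effect-size null distributions under random subtype regrouping.

    Each permutation shuffles case samples into pseudo-subtypes of the
    given sizes and records Cohen's d (vs controls) per transcript; per
    pseudo-subtype, the per-permutation empirical distributions are
    combined by averaging each quantile on a fixed grid.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    X, _ = _group_arrays(case_expr, control_expr)
    sizes = np.asarray(subtype_sizes, dtype=int)
    if sizes.sum() != X.shape[1]:
        raise ValueError(f"subtype sizes sum to {sizes.sum()}, expected {X.shape[1]}")
    rng = np.random.default_rng(seed)
    grid = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    bounds = np.concatenate([[0], np.cumsum(sizes)])

    acc = np.zeros((len(sizes), n_quantiles))
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[1])
        for s in range(len(sizes)):
            cols = perm[bounds[s]:bounds[s + 1]]
            d = cohens_d(X[:, cols], control_expr)
            acc[s] += np.quantile(d[~np.isnan(d)], grid)
    null_q = pd.DataFrame(
        (acc / n_perm).T,
        columns=[f"pseudo_subtype_{s + 1}" for s in range(len(sizes))])

    d_all = cohens_d(X, control_expr)
    all_q = np.quantile(d_all[~np.isnan(d_all)], grid)

    observed_q = None
    if observed_labels is not None:
        labels = np.asarray(observed_labels).ravel()
        cols = {}
        for value in np.unique(labels):
            d_obs = cohens_d(X[:, labels == value], control_expr)
            cols[f"subtype_{value}"] = np.quantile(d_obs[~np.isnan(d_obs)], grid)
        observed_q = pd.DataFrame(cols)

    return PermutationValidationResult(
        quantile_grid=grid,
        null_quantiles=null_q,
        all_cases_quantiles=all_q,
        observed_quantiles=observed_q,
        n_perm=n_perm,
    )


def mgl_qtl(mgl, geno: pd.DataFrame, alpha: float = 1e-4) -> pd.DataFrame:
    """Regress one metagene expression level on every SNP's dosage.

    Simple linear regression ``MGL ~ intercept + dosage`` per SNP; the
    two-sided p-value uses the t distribution with n-2 degrees of freedom.
    The u-allele (the allele raising the MGL) is the minor (coded) allele
    when the slope is positive, the major allele otherwise.  Constant-dosage
    SNPs are skipped with a warning.
    """
    y = np.asarray(mgl, dtype=float).ravel()
    G = geno.to_numpy(dtype=float)
    if G.shape[1] != y.size:
        raise ValueError("genotype samples do not match MGL length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for the n-2 df t-test")
    g_var = G.var(axis=1)
    constant = g_var == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant-dosage SNPs skipped", stacklevel=2)
    Gc = G - G.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (Gc @ yc) / (Gc * Gc).sum(axis=1)
        resid_ss = (yc * yc).sum() - slope**2 * (Gc * Gc).sum(axis=1)
        sigma2 = np.maximum(resid_ss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / (Gc * Gc).sum(axis=1))
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    out = pd.DataFrame({
        "slope": slope,
        "t": tstat,
        "p": p,
        "u_allele": np.where(slope > 0, "minor", "major"),
        "significant": p < alpha,
    }, index=geno.index)
    out.loc[constant, ["slope", "t", "p"]] = np.nan
    out.loc[constant, "u_allele"] = "undefined"
    out.loc[constant, "significant"] = False
    return out


def u_allele_frequencies(
    qtl: pd.DataFrame | Dict[str, pd.DataFrame],
    geno: pd.DataFrame,
    partition,
) -> pd.DataFrame:
    """Mean u-allele frequency of each MGL-QTL set within each subtype.

    For one MGL's significant SNPs, a subtype's u-allele frequency at a SNP
    is ``sum(codes) / (2 n_s)`` when the u-allele is the coded minor allele
    and one minus that otherwise; the table reports the mean over the set.
    """
    if isinstance(qtl, pd.DataFrame):
        qtl = {"MGL1": qtl}
    labels = np.asarray(partition).ravel()
    if labels.size != geno.shape[1]:
        raise ValueError("partition length does not match genotype samples")
    rows = []
    for mgl_name, table in qtl.items():
        sig = table.index[table["significant"] & (table["u_allele"] != "undefined")]
        if len(sig) == 0:
            warnings.warn(f"{mgl_name}: no significant SNPs; skipped", stacklevel=2)
            continue
        sub = geno.loc[sig]
        minor_is_u = (table.loc[sig, "u_allele"] == "minor").to_numpy()
        for value in np.unique(labels):
            cols = labels == value
            if not cols.any():
                continue
            p_minor = sub.loc[:, cols].to_numpy().sum(axis=1) / (2.0 * cols.sum())
            freq = np.where(minor_is_u, p_minor, 1.0 - p_minor)
            rows.append({"mgl": mgl_name, "subtype": value,
                         "n_snps": len(sig), "mean_u_freq": float(freq.mean())})
    return pd.DataFrame(rows)
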