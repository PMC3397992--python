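"""Expression and genotype preprocessing filters.

The pipeline order is fixed: drop transcripts with too many missing values,
log2-transform, keep transcripts passing mean/variance percentile filters,
mean-impute the survivors, and drop SNPs with low minor-allele frequency.
Every stage appends its before/after counts to a :class:`FilterReport`.
Missing expression values are encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "filter_missing_transcripts",
    "log2_transform",
    "filter_expression_percentiles",
    "impute_mean",
    "filter_snps_maf",
    "preprocess_expression",
]


@dataclass
class FilterReport:
    """Before/after feature counts per stage; counts never increase."""

    stages: List[dict] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_after: int, **params) -> None:
        if n_after > n_before:
            raise ValueError("filter stage increased the feature count")
        self.stages.append({"stage": name, "n_before": n_before,
                            "n_after": n_after, **params})

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def __str__(self) -> str:
        return self.table().to_string(index=False) if self.stages else "(no stages)"


def filter_missing_transcripts(
    expr: pd.DataFrame, max_missing_frac: float = 0.30,
    report: FilterReport | None = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Drop transcripts whose missing fraction exceeds ``max_missing_frac``."""
    report = report or FilterReport()
    frac = expr.isna().mean(axis=1)
    kept = expr.loc[frac <= max_missing_frac]
    report.add("missing_filter", len(expr), len(kept),
               max_missing_frac=max_missing_frac)
    return kept, report


def log2_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; non-positive observed values are an error."""
    bad = (expr <= 0).any(axis=None)
    if bad:
        offenders = expr.stack()[expr.stack() <= 0]
        raise ValueError(
            f"log2 transform requires positive values; offending entries: "
            f"{list(offenders.index[:10])}"
        )
    return np.log2(expr)


def filter_expression_percentiles(
    expr: pd.DataFrame,
    mean_pct: float = 70.0,
    var_pct: float = 50.0,
    *,
    interpretation: str = "top-fraction",
    report: FilterReport | None = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Keep transcripts by per-transcript mean and variance percentiles.

    Both statistics are computed on the input (over observed values) before
    any removal, with linear-interpolation quantiles and ties kept (``>=``).
    Two readings of "upper Pth percentile" are supported:

    - ``top-fraction`` (default): the top P% of transcripts, i.e. statistic
      >= the (100-P)th percentile;
    - ``above-percentile``: statistic >= the Pth percentile (top (100-P)%).

    A percentile of 0 disables that filter in either interpretation.
    """
    report = report or FilterReport()
    means = expr.mean(axis=1)
    variances = expr.var(axis=1, ddof=1)
    if interpretation == "top-fraction":
        mean_cut = -np.inf if mean_pct <= 0 else np.percentile(means, 100.0 - mean_pct)
        var_cut = -np.inf if var_pct <= 0 else np.percentile(variances, 100.0 - var_pct)
    elif interpretation == "above-percentile":
        mean_cut = -np.inf if mean_pct <= 0 else np.percentile(means, mean_pct)
        var_cut = -np.inf if var_pct <= 0 else np.percentile(variances, var_pct)
    else:
        raise ValueError("interpretation must be 'top-fraction' or 'above-percentile'")
    keep = (means >= mean_cut) & (variances >= var_cut)
    kept = expr.loc[keep]
    report.add("percentile_filter", len(expr), len(kept), mean_pct=mean_pct,
               var_pct=var_pct, interpretation=interpretation)
    return kept, report


def impute_mean(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing value by its transcript's observed mean."""
    all_missing = expr.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"transcripts with no observed values cannot be imputed: "
            f"{list(expr.index[all_missing][:10])}"
        )
    means = expr.mean(axis=1)
    return expr.apply(lambda row: row.fillna(means[row.name]), axis=1)


def filter_snps_maf(
    geno: pd.DataFrame, min_maf: float = 0.10,
    report: FilterReport | None = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Drop SNPs with minor-allele frequency below ``min_maf``.

    MAF = min(p, 1-p) with p the coded-allele frequency sum(codes)/(2n).
    """
    report = report or FilterReport()
    codes = geno.to_numpy()
    if not np.isin(codes, (0, 1, 2)).all():
        raise ValueError("genotype codes must be 0, 1 or 2")
    p = codes.sum(axis=1) / (2.0 * geno.shape[1])
    maf = np.minimum(p, 1.0 - p)
    kept = geno.loc[maf >= min_maf]
    report.add("maf_filter", len(geno), len(kept), min_maf=min_maf)
    return kept, report


def preprocess_expression(
    expr: pd.DataFrame,
    *,
    max_missing_frac: float = 0.30,
    mean_pct: float = 70.0,
    var_pct: float = 50.0,
    interpretation: str = "top-fraction",
    allow_shift: bool = False,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Full expression pipeline: missing-filter, log2, percentile-filter, impute.

    The output has no missing values and is suitable NMF input; a negative
    log2 value raises unless ``allow_shift`` adds a global constant making
    the matrix non-negative.
    """
    out, report = filter_missing_transcripts(expr, max_missing_frac)
    out = log2_transform(out)
    out, report = filter_expression_percentiles(
        out, mean_pct, var_pct, interpretation=interpretation, report=report)
    out = impute_mean(out)
    if (out.to_numpy() < 0).any():
        if not allow_shift:
            raise ValueError(
                "log2 expression contains negative values; pass allow_shift=True "
                "to add a global constant before NMF")
        out = out - out.to_numpy().min()
    return out, report
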