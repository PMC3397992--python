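"""ARI-driven informative-transcript selection.

The coefficients of the NMF basis matrix ``W`` rank how strongly each
transcript loads on each metagene.  For a grid of cut-offs ``t`` the union
of the per-metagene top-``t`` transcripts is taken, the factorization is
re-run on that subset, and the resulting subtyping is compared with the
all-transcript reference partition by the adjusted Rand index.  The minimal
``t`` whose subset preserves the reference subtyping (ARI at or above a
threshold, default 0.95) defines the informative-transcript set; removing
transcripts shared between metagenes then yields metagene-specific sets —
the endophenotype candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .metrics import adjusted_rand_index, contingency_table
from .nmf import KLNMF, KLNMFResults

__all__ = [
    "rank_transcripts",
    "top_t_union",
    "select_optimal_t",
    "metagene_specific",
    "match_labels",
    "count_misclassified",
    "SelectionReport",
]


def _as_W_frame(W) -> pd.DataFrame:
    if isinstance(W, pd.DataFrame):
        return W
    W = np.asarray(W, dtype=float)
    return pd.DataFrame(W, index=[f"t{i}" for i in range(W.shape[0])],
                        columns=[f"metagene_{a + 1}" for a in range(W.shape[1])])


def rank_transcripts(W) -> Dict[str, List]:
    """Per-metagene transcript ordering by descending coefficient.

    Stable: ties keep the input (transcript id) order.  Rescaling a column
    by a positive constant leaves its ordering unchanged.
    """
    frame = _as_W_frame(W)
    out: Dict[str, List] = {}
    for col in frame.columns:
        order = np.argsort(-frame[col].to_numpy(), kind="stable")
        out[col] = list(frame.index[order])
    return out


def top_t_union(W, t: int) -> List:
    """Union of each metagene's top-``t`` transcripts, in matrix row order."""
    frame = _as_W_frame(W)
    if not 1 <= t <= frame.shape[0]:
        raise ValueError(f"t must be in [1, {frame.shape[0]}], got {t}")
    ranked = rank_transcripts(frame)
    chosen = set()
    for col in frame.columns:
        chosen.update(ranked[col][:t])
    return [tid for tid in frame.index if tid in chosen]


def match_labels(labels, reference) -> np.ndarray:
    """Relabel ``labels`` to best agree with ``reference`` (Hungarian).

    Maximizes the matched contingency-table trace; extra clusters keep
    fresh labels.
    """
    labels = np.asarray(labels).ravel()
    reference = np.asarray(reference).ravel()
    table = contingency_table(labels, reference)
    pred_values = np.unique(labels)
    ref_values = np.unique(reference)
    rows, cols = linear_sum_assignment(-table)
    mapping = {pred_values[r]: ref_values[c] for r, c in zip(rows, cols)}
    unmatched = [v for v in pred_values if v not in mapping]
    spare = iter([v for v in range(1, len(pred_values) + len(ref_values) + 1)
                  if v not in set(mapping.values())])
    for v in unmatched:
        mapping[v] = next(spare)
    return np.asarray([mapping[v] for v in labels])


def count_misclassified(labels, reference) -> int:
    """Disagreements after optimal (Hungarian) label alignment."""
    return int(np.sum(match_labels(labels, reference) != np.asarray(reference).ravel()))


def metagene_specific(W, chosen_t: int) -> Dict[str, List]:
    """Per-metagene top-``chosen_t`` lists with shared transcripts removed.

    A transcript appearing in two or more metagenes' top lists is dropped
    from all of them, so the returned sets are pairwise disjoint.
    """
    frame = _as_W_frame(W)
    ranked = rank_transcripts(frame)
    tops = {col: ranked[col][:chosen_t] for col in frame.columns}
    counts: Dict = {}
    for ids in tops.values():
        for tid in ids:
            counts[tid] = counts.get(tid, 0) + 1
    return {col: [tid for tid in ids if counts[tid] == 1] for col, ids in tops.items()}


@dataclass
class SelectionReport:
    """Selection-grid table, chosen cut-off and metagene-specific sets."""

    table: pd.DataFrame          # columns: t, union_size, ari, misclassified
    chosen_t: int | None
    metagene_specific: Dict[str, List]
    reference_labels: np.ndarray
    ari_threshold: float
    subset_results: Dict[int, KLNMFResults] = field(default_factory=dict, repr=False)
    reference_result: KLNMFResults | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = ["Informative-transcript selection",
                 self.table.to_string(index=False)]
        if self.chosen_t is None:
            lines.append(f"no t reached ARI >= {self.ari_threshold}")
        else:
            sizes = {k: len(v) for k, v in self.metagene_specific.items()}
            lines.append(f"chosen t = {self.chosen_t} "
                         f"(minimum t with ARI >= {self.ari_threshold})")
            lines.append(f"metagene-specific set sizes: {sizes}")
        return "\n".join(lines)

    def metagene_correlations(self) -> Dict[str, float]:
        """Pearson r between subset and full-data metagene expression.

        Rows of the chosen subset's H are aligned to the reference H by the
        Hungarian matching of their argmax partitions, then correlated
        sample-wise.
        """
        if self.chosen_t is None or self.reference_result is None:
            raise ValueError("no chosen_t or missing reference factors")
        sub = self.subset_results[self.chosen_t]
        ref = self.reference_result
        table = contingency_table(sub.assign_clusters(), ref.assign_clusters())
        rows, cols = linear_sum_assignment(-table)
        out = {}
        for r, c in zip(rows, cols):
            if r < sub.k and c < ref.k:
                rho = pearsonr(sub.H[r], ref.H[c]).statistic
                out[f"MGL{c + 1}"] = float(rho)
        return out


def select_optimal_t(
    V,
    k: int,
    t_grid: Sequence[int] = (50, 100, 150, 200, 250, 300, 400, 800),
    ari_threshold: float = 0.95,
    seed: int | None = None,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
    reference: KLNMFResults | None = None,
) -> SelectionReport:
    """Scan a grid of top-``t`` cut-offs and pick the minimal faithful one.

    For each ``t`` the expression matrix is restricted to the top-``t``
    union, re-factorized with a seed derived from ``(seed, t)``, and its
    argmax partition compared against the all-transcript reference by ARI
    and by misclassification count after Hungarian alignment.  When the
    union covers every transcript the reference factors are reused (same
    data, same seed policy).  ``chosen_t`` is the minimum ``t`` with
    ``ARI >= ari_threshold``; None if no t qualifies.
    """
    if not isinstance(V, pd.DataFrame):
        V = pd.DataFrame(np.asarray(V, dtype=float))
    m = V.shape[0]
    base = 0 if seed is None else int(seed)
    if reference is None:
        ref_rng = np.random.default_rng(np.random.SeedSequence((base, 0)))
        reference = KLNMF(V, k).fit(seed=ref_rng, max_iter=max_iter, tol=tol)
    ref_labels = reference.assign_clusters()
    W_ref = reference.W_frame()
    W_ref.index = V.index

    rows = []
    subset_results: Dict[int, KLNMFResults] = {}
    for t in sorted(set(int(t) for t in t_grid)):
        t_eff = min(t, m)
        union = top_t_union(W_ref, t_eff)
        if len(union) <= k:
            warnings.warn(f"t={t}: union of {len(union)} transcripts cannot "
                          f"support a rank-{k} factorization, skipped", stacklevel=2)
            continue
        if len(union) == m:
            result = reference
        else:
            rng = np.random.default_rng(np.random.SeedSequence((base, t)))
            result = KLNMF(V.loc[union], k).fit(seed=rng, max_iter=max_iter, tol=tol)
        labels = result.assign_clusters()
        rows.append({
            "t": t,
            "union_size": len(union),
            "ari": adjusted_rand_index(labels, ref_labels),
            "misclassified": count_misclassified(labels, ref_labels),
        })
        subset_results[t] = result
    table = pd.DataFrame(rows)
    chosen_t: int | None = None
    if len(table):
        qualifying = table.loc[table["ari"] >= ari_threshold, "t"]
        if len(qualifying):
            chosen_t = int(qualifying.min())
    specific = metagene_specific(W_ref, chosen_t) if chosen_t is not None else {}
    return SelectionReport(
        table=table,
        chosen_t=chosen_t,
        metagene_specific=specific,
        reference_labels=ref_labels,
        ari_threshold=ari_threshold,
        subset_results=subset_results,
        reference_result=reference,
    )
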