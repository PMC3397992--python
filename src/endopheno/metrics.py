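"""Partition-agreement statistics: adjusted Rand index and purity."""

from __future__ import annotations

import numpy as np
from scipy.special import comb

__all__ = ["adjusted_rand_index", "purity", "contingency_table"]


def _check_pair(p1, p2):
    a = np.asarray(p1).ravel()
    b = np.asarray(p2).ravel()
    if a.shape != b.shape:
        raise ValueError(f"partition lengths differ: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("partitions are empty")
    return a, b


def contingency_table(p1, p2) -> np.ndarray:
    """Cross-tabulation of two partitions over the same samples."""
    a, b = _check_pair(p1, p2)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def adjusted_rand_index(p1, p2) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Chance-corrected pair-counting agreement; 1 for identical partitions
    (up to relabelling), ~0 for independent ones, negative values possible.
    When both partitions are trivial (all pairs agree by construction) the
    index is 1 by convention.
    """
    table = contingency_table(p1, p2)
    n = table.sum()
    sum_ij = comb(table, 2).sum()
    a = comb(table.sum(axis=1), 2).sum()
    b = comb(table.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = 0.5 * (a + b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def purity(predicted, truth) -> float:
    """Fraction of samples whose predicted cluster's majority class is theirs.

    ``(1/n) * sum over predicted clusters q of max_r |q intersect r|``;
    ranges from 1/k (uninformative) to 1 (perfect recovery, labels aside).
    """
    table = contingency_table(predicted, truth)
    return float(table.max(axis=1).sum() / table.sum())
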