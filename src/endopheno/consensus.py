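"""Consensus clustering over NMF restarts and cophenetic rank selection.

For a candidate rank ``k`` the factorization is repeated from many random
starts; the consensus matrix is the fraction of runs in which each pair of
samples lands in the same argmax-H cluster.  Cluster stability is scored by
the cophenetic correlation coefficient rho: the Pearson correlation between
the consensus distance ``1 - C`` and the cophenetic distances of its
average-linkage dendrogram.  The rank with the largest rho (smallest such k
on ties) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import squareform

from .nmf import KLNMF

__all__ = [
    "connectivity_matrix",
    "consensus_matrix",
    "cophenetic_coefficient",
    "select_rank",
    "ConsensusResult",
    "RankSelectionResult",
]


def connectivity_matrix(labels) -> np.ndarray:
    """Binary co-membership matrix: 1 iff two samples share a cluster."""
    labels = np.asarray(labels).ravel()
    return (labels[:, None] == labels[None, :]).astype(float)


@dataclass
class ConsensusResult:
    """Consensus matrix for one rank, its stability score and leaf order."""

    k: int
    consensus: np.ndarray
    rho: float
    n_runs: int
    reorder_index: np.ndarray

    def reordered(self) -> np.ndarray:
        idx = self.reorder_index
        return self.consensus[np.ix_(idx, idx)]


def cophenetic_coefficient(consensus: np.ndarray) -> tuple[float, np.ndarray]:
    """Cophenetic correlation of a consensus matrix, plus the leaf order.

    Average-linkage hierarchical clustering is run on ``d = 1 - C``; rho is
    the Pearson correlation between the off-diagonal entries of ``d`` and
    the dendrogram's cophenetic distances.  If ``d`` has zero variance (all
    samples identical) rho is 1 by convention.
    """
    consensus = np.asarray(consensus, dtype=float)
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    tree = linkage(condensed, method="average")
    order = leaves_list(tree)
    if condensed.std() == 0:
        warnings.warn("consensus distances are constant; rho = 1 by convention",
                      stacklevel=2)
        return 1.0, order
    rho, _ = cophenet(tree, condensed)
    return float(rho), order


def consensus_matrix(
    V,
    k: int,
    n_runs: int = 50,
    seed: int | np.random.SeedSequence | None = None,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Average connectivity over ``n_runs`` independently seeded NMF runs.

    Failed runs are dropped with a warning; at least two must survive.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seedseq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    model = KLNMF(V, k)
    n = model.V.shape[1]
    acc = np.zeros((n, n))
    survived = 0
    for child in seedseq.spawn(n_runs):
        try:
            res = model.fit(seed=np.random.default_rng(child),
                            max_iter=max_iter, tol=tol)
            acc += connectivity_matrix(res.assign_clusters())
            survived += 1
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"NMF run failed and was dropped: {exc}", stacklevel=2)
    if survived < 2:
        raise RuntimeError("fewer than 2 NMF runs survived; cannot build consensus")
    consensus = acc / survived
    rho, order = cophenetic_coefficient(consensus)
    return ConsensusResult(k=k, consensus=consensus, rho=rho,
                           n_runs=survived, reorder_index=order)


@dataclass
class RankSelectionResult:
    """(k, rho) table over candidate ranks and the selected rank."""

    table: pd.DataFrame
    best_k: int
    consensus_by_k: dict

    def summary(self) -> str:
        lines = ["Cophenetic rank selection", self.table.to_string(index=False)]
        lines.append(f"selected k* = {self.best_k} (largest rho, smallest k on ties)")
        return "\n".join(lines)


def select_rank(
    V,
    k_min: int = 2,
    k_max: int = 5,
    n_runs: int = 50,
    seed: int | None = None,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> RankSelectionResult:
    """Score each rank in ``[k_min, k_max]`` by consensus stability.

    k* is the smallest rank attaining the maximum cophenetic rho.  Each
    rank uses its own seed stream derived from ``(seed, k)``, so the rho of
    a given k does not depend on the range requested.
    """
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    rows = []
    consensus_by_k = {}
    for k in range(k_min, k_max + 1):
        child = np.random.SeedSequence((0 if seed is None else int(seed), k))
        result = consensus_matrix(V, k, n_runs=n_runs, seed=child,
                                  max_iter=max_iter, tol=tol)
        consensus_by_k[k] = result
        rows.append({"k": k, "rho": result.rho, "n_runs": result.n_runs})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["rho"].idxmax(), "k"])
    return RankSelectionResult(table=table, best_k=best_k,
                               consensus_by_k=consensus_by_k)
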