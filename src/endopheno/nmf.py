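"""KL-divergence non-negative matrix factorization with metagene clustering.

Factorizes a non-negative expression matrix ``V`` (m transcripts x n
samples) as ``V ~ W H`` with ``W`` (m x k) holding metagene coefficients and
``H`` (k x n) holding per-sample metagene expression levels (MGLs), by
minimizing the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

with the classical multiplicative updates, which never increase D.  Each
sample is assigned to the metagene with the largest entry in its column of
``H``; those argmax groups are the molecular subtypes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["kl_divergence", "KLNMF", "KLNMFResults", "nmf_factorize", "assign_clusters"]

_EPS = 1e-12


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray, *, eps: float = _EPS) -> float:
    """Generalized KL divergence D(V || WH), with the convention 0 log 0 = 0.

    An ``eps`` floor inside the logarithm guards (WH)_ij = 0; inputs must be
    non-negative.
    """
    V = np.asarray(V, dtype=float)
    WH = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    ratio = V / np.maximum(WH, eps)
    log_term = np.where(V > 0, V * np.log(np.maximum(ratio, eps)), 0.0)
    return float(np.sum(log_term - V + WH))


class KLNMF:
    """KL-divergence NMF model for a non-negative matrix.

    Parameters
    ----------
    V : DataFrame or ndarray
        Non-negative transcripts x samples matrix with no missing values.
    rank : int
        Number of metagenes k, with ``1 <= k < min(m, n)``.

    ``fit`` runs multiplicative updates from a random start and returns a
    :class:`KLNMFResults`.
    """

    def __init__(self, V, rank: int):
        if isinstance(V, pd.DataFrame):
            self.transcript_ids: Sequence | None = list(V.index)
            self.sample_ids: Sequence | None = list(V.columns)
            data = V.to_numpy(dtype=float)
        else:
            self.transcript_ids = None
            self.sample_ids = None
            data = np.asarray(V, dtype=float)
        if data.ndim != 2:
            raise ValueError("V must be a 2-D matrix")
        if np.isnan(data).any():
            raise ValueError("V contains missing values; impute before factorizing")
        if (data < 0).any():
            raise ValueError("V contains negative entries; NMF input must be non-negative")
        if not 1 <= rank < min(data.shape):
            raise ValueError(f"rank must satisfy 1 <= k < min(m, n) = {min(data.shape)}")
        self.V = data
        self.rank = int(rank)

    def fit(
        self,
        *,
        seed: int | np.random.SeedSequence | np.random.Generator | None = None,
        max_iter: int = 2000,
        tol: float = 1e-6,
        patience: int = 10,
    ) -> "KLNMFResults":
        """Run multiplicative updates until convergence or ``max_iter``.

        Convergence: relative divergence change below ``tol`` for
        ``patience`` consecutive sweeps.  ``seed`` controls the uniform
        random initialization (entries on (0, 1] scaled by mean(V)/k).
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        V, k = self.V, self.rank
        m, n = V.shape
        scale = max(V.mean() / k, _EPS)
        W = (1.0 - rng.random((m, k))) * scale
        H = (1.0 - rng.random((k, n))) * scale

        # constants of D(V||WH) = sum(V log V) - sum(V log WH) - sum(V) + sum(WH)
        v_sum = V.sum()
        with np.errstate(divide="ignore"):
            vlogv = np.where(V > 0, V * np.log(np.maximum(V, _EPS)), 0.0).sum()

        def divergence(WH: np.ndarray) -> float:
            return float(vlogv - (V * np.log(WH)).sum() - v_sum + WH.sum())

        WH = np.maximum(W @ H, _EPS)
        trace = [divergence(WH)]
        flat = 0
        for _ in range(max_iter):
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
            WH = np.maximum(W @ H, _EPS)
            d = divergence(WH)
            prev = trace[-1]
            trace.append(d)
            rel = abs(prev - d) / max(abs(prev), _EPS)
            flat = flat + 1 if rel < tol else 0
            if flat >= patience:
                break
        return KLNMFResults(
            model=self,
            W=W,
            H=H,
            divergence_trace=np.asarray(trace),
            converged=flat >= patience,
        )

    def fit_best(
        self,
        n_restarts: int = 5,
        *,
        seed: int | np.random.SeedSequence | None = None,
        **fit_kwargs,
    ) -> "KLNMFResults":
        """Best of ``n_restarts`` independently seeded fits by final divergence.

        Multiplicative updates only find local optima; restarting guards
        against a poor random start.  Deterministic given ``seed``.
        """
        seedseq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        best: KLNMFResults | None = None
        for child in seedseq.spawn(n_restarts):
            res = self.fit(seed=np.random.default_rng(child), **fit_kwargs)
            if best is None or res.final_divergence < best.final_divergence:
                best = res
        assert best is not None
        return best


class KLNMFResults:
    """Fitted factors, divergence trace and subtype assignment."""

    def __init__(self, model: KLNMF, W: np.ndarray, H: np.ndarray,
                 divergence_trace: np.ndarray, converged: bool):
        self.model = model
        self.W = W
        self.H = H
        self.k = model.rank
        self.divergence_trace = divergence_trace
        self.converged = converged

    @property
    def n_iter(self) -> int:
        return len(self.divergence_trace) - 1

    @property
    def final_divergence(self) -> float:
        return float(self.divergence_trace[-1])

    @property
    def labels(self) -> np.ndarray:
        return self.assign_clusters()

    def assign_clusters(self) -> np.ndarray:
        """1-based subtype label per sample: argmax over metagenes of H.

        Ties break to the lowest metagene index.  A structurally all-zero
        column of H (no metagene expressed) is unassignable and labelled 0;
        ``n_unassigned`` reports how many.
        """
        labels = np.argmax(self.H, axis=0) + 1
        dead = ~np.any(self.H > 0, axis=0)
        labels[dead] = 0
        self._n_unassigned = int(dead.sum())
        return labels

    @property
    def n_unassigned(self) -> int:
        self.assign_clusters()
        return self._n_unassigned

    def W_frame(self) -> pd.DataFrame:
        cols = [f"metagene_{a + 1}" for a in range(self.k)]
        idx = self.model.transcript_ids
        return pd.DataFrame(self.W, index=idx, columns=cols)

    def H_frame(self) -> pd.DataFrame:
        rows = [f"MGL{a + 1}" for a in range(self.k)]
        return pd.DataFrame(self.H, index=rows, columns=self.model.sample_ids)

    def normalized_W(self) -> pd.DataFrame:
        """Column-stochastic W for reporting; not used in assignment."""
        frame = self.W_frame()
        sums = frame.sum(axis=0).replace(0.0, np.nan)
        return frame / sums

    def summary(self) -> str:
        labels = self.assign_clusters()
        sizes = {f"cluster {c}": int((labels == c).sum()) for c in range(1, self.k + 1)}
        lines = [
            "KL-NMF factorization",
            f"  shape            : {self.model.V.shape[0]} transcripts x "
            f"{self.model.V.shape[1]} samples",
            f"  rank (metagenes) : {self.k}",
            f"  iterations       : {self.n_iter} "
            f"({'converged' if self.converged else 'max_iter reached'})",
            f"  final divergence : {self.final_divergence:.6g}",
            f"  cluster sizes    : {sizes}",
        ]
        if self.n_unassigned:
            lines.append(f"  unassigned       : {self.n_unassigned}")
        return "\n".join(lines)


def nmf_factorize(V, k: int, seed=None, max_iter: int = 2000, tol: float = 1e-6) -> KLNMFResults:
    """Functional wrapper: fit :class:`KLNMF` and return its results."""
    return KLNMF(V, k).fit(seed=seed, max_iter=max_iter, tol=tol)


def assign_clusters(factors) -> np.ndarray:
    """Argmax-of-H subtype labels from results or a raw H matrix."""
    if isinstance(factors, KLNMFResults):
        return factors.assign_clusters()
    H = np.asarray(factors, dtype=float)
    labels = np.argmax(H, axis=0) + 1
    labels[~np.any(H > 0, axis=0)] = 0
    return labels
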