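"""Genotype-coupled expression simulator with planted molecular subtypes.

The generative model mimics a bulk microarray experiment in which molecular
subtypes are driven by common genetic variants.  Every gene has log2-scale
baseline mean ``mu`` (default ``log2(100)``) and multivariate-normal noise
with an equicorrelated block covariance (one block per subtype, genes across
blocks independent).  A fraction ``pi`` of genes is non-informative:

    x_gj = mu + eps_gj

Each remaining (informative) gene is tied one-to-one to a SNP under an
additive genetic model (minor-allele dosage 0/1/2):

    x_gj = mu + beta * G_gj + eps_gj

Subtype structure enters only through allele frequencies: the SNPs attached
to subtype ``s`` have minor-allele frequency ``baseline_maf + delta_maf`` in
samples of subtype ``s`` and ``baseline_maf`` everywhere else, so the
expected expression shift separating subtype ``s`` is ``2 * beta * delta_maf``.
Genotypes are drawn from the Hardy-Weinberg trinomial
``((1-p)^2, 2p(1-p), p^2)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "block_covariance",
    "simulate_expression",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-subtype generative model.

    Defaults are the reference study conditions: 3 subtypes x 80 samples,
    160 informative genes per subtype, 70% non-informative genes, per-gene
    variance 0.3 with block equicorrelation drawn from [0.4, 0.6], baseline
    MAF 0.1 and baseline log2 mean log2(100).
    """

    n_subtypes: int = 3
    samples_per_subtype: int = 80
    informative_genes_per_subtype: int = 160
    pi_noninformative: float = 0.7
    delta_maf: float = 0.5
    beta: float = 0.5
    baseline_maf: float = 0.1
    gene_variance: float = 0.3
    corr_range: Tuple[float, float] = (0.4, 0.6)
    baseline_log_mean: float = math.log2(100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subtypes, self.samples_per_subtype,
               self.informative_genes_per_subtype) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.pi_noninformative < 1.0:
            raise ValueError("pi_noninformative must be in [0, 1)")
        if self.baseline_maf < 0 or self.delta_maf < 0:
            raise ValueError("allele frequencies must be non-negative")
        if self.baseline_maf + self.delta_maf > 1.0:
            raise ValueError(
                f"baseline_maf + delta_maf = "
                f"{self.baseline_maf + self.delta_maf:.3f} exceeds 1"
            )
        lo, hi = self.corr_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("corr_range must satisfy 0 <= low <= high < 1")
        if self.gene_variance <= 0:
            raise ValueError("gene_variance must be positive")

    # ---- derived sizes -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.n_subtypes * self.samples_per_subtype

    @property
    def n_informative_genes(self) -> int:
        return self.n_subtypes * self.informative_genes_per_subtype

    @property
    def n_total_genes(self) -> int:
        # total count chosen so non-informative genes form fraction pi
        return int(round(self.n_informative_genes / (1.0 - self.pi_noninformative)))

    @property
    def n_noninformative_genes(self) -> int:
        return self.n_total_genes - self.n_informative_genes


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``subtype_labels`` is a 1-based label per sample; informative gene/SNP
    ids are disjoint across subtypes; ``rho_blocks`` records the
    equicorrelation drawn for each covariance block.
    """

    subtype_labels: np.ndarray
    sample_ids: List[str]
    informative_gene_index: Dict[int, List[str]]
    informative_snp_index: Dict[int, List[str]]
    config: SimulationConfig
    rho_blocks: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for ids in self.informative_gene_index.values():
            overlap = seen.intersection(ids)
            if overlap:
                raise ValueError(f"informative gene sets overlap: {overlap}")
            seen.update(ids)


# ---------------------------------------------------------------------------
# seed plumbing: one global seed, independent sub-streams per component
# ---------------------------------------------------------------------------

def _substreams(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("genotypes", "rho", "noise")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _ids(prefix: str, n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _subtype_labels(config: SimulationConfig) -> np.ndarray:
    return np.repeat(np.arange(1, config.n_subtypes + 1), config.samples_per_subtype)


def gene_blocks(config: SimulationConfig) -> List[Tuple[str, np.ndarray]]:
    """Partition gene indices into equicorrelation blocks.

    Informative genes form one block per subtype; non-informative genes are
    split into ``n_subtypes`` near-equal blocks, preserving the
    block-diagonal covariance layout.
    """
    blocks: List[Tuple[str, np.ndarray]] = []
    g = config.informative_genes_per_subtype
    for s in range(config.n_subtypes):
        blocks.append((f"informative_T{s + 1}", np.arange(s * g, (s + 1) * g)))
    start = config.n_informative_genes
    sizes = np.full(config.n_subtypes, config.n_noninformative_genes // config.n_subtypes)
    sizes[: config.n_noninformative_genes % config.n_subtypes] += 1
    for s, size in enumerate(sizes):
        blocks.append((f"noninformative_{s + 1}", np.arange(start, start + size)))
        start += size
    return blocks


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Tuple[pd.DataFrame, SimulationTruth]:
    """Draw one SNP per informative gene under Hardy-Weinberg equilibrium.

    For the SNPs attached to subtype ``s``, samples of subtype ``s`` use
    minor-allele frequency ``baseline_maf + delta_maf``; all other samples
    use ``baseline_maf``.  Returns a SNPs x samples dosage matrix (codes
    0/1/2) and the ground truth.
    """
    if rng is None:
        rng = _substreams(config.seed)["genotypes"]
    labels = _subtype_labels(config)
    sample_ids = _ids("S", config.n_samples)
    gene_ids = _ids("gene", config.n_total_genes)
    snp_ids = _ids("snp", config.n_informative_genes)

    p = np.full((config.n_informative_genes, config.n_samples), config.baseline_maf)
    g = config.informative_genes_per_subtype
    gene_index: Dict[int, List[str]] = {}
    snp_index: Dict[int, List[str]] = {}
    for s in range(1, config.n_subtypes + 1):
        rows = slice((s - 1) * g, s * g)
        p[rows, labels == s] = config.baseline_maf + config.delta_maf
        gene_index[s] = gene_ids[(s - 1) * g: s * g]
        snp_index[s] = snp_ids[(s - 1) * g: s * g]

    codes = rng.binomial(2, p)  # HWE trinomial == Binomial(2, p) per genotype
    geno = pd.DataFrame(codes, index=snp_ids, columns=sample_ids)
    truth = SimulationTruth(
        subtype_labels=labels,
        sample_ids=sample_ids,
        informative_gene_index=gene_index,
        informative_snp_index=snp_index,
        config=config,
    )
    return geno, truth


def draw_block_correlations(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Dict[str, float]:
    """Draw one equicorrelation per covariance block, uniform on corr_range."""
    if rng is None:
        rng = _substreams(config.seed)["rho"]
    lo, hi = config.corr_range
    return {name: float(rng.uniform(lo, hi)) for name, _ in gene_blocks(config)}


def block_covariance(
    config: SimulationConfig,
    n_genes: int | None = None,
    rho_blocks: Dict[str, float] | None = None,
) -> np.ndarray:
    """Dense block-diagonal covariance of the gene noise.

    Within each block the diagonal is ``gene_variance`` and the off-diagonal
    is ``gene_variance * rho_block``; distinct blocks are independent.  The
    result is symmetric positive-definite because every equicorrelation
    satisfies ``-1/(size-1) < rho < 1``.
    """
    if n_genes is None:
        n_genes = config.n_total_genes
    if n_genes != config.n_total_genes:
        raise ValueError(
            f"n_genes={n_genes} does not match the configured partition "
            f"({config.n_total_genes} genes)"
        )
    if rho_blocks is None:
        rho_blocks = draw_block_correlations(config)
    cov = np.zeros((n_genes, n_genes))
    v = config.gene_variance
    for name, idx in gene_blocks(config):
        rho = rho_blocks[name]
        block = np.full((idx.size, idx.size), v * rho)
        np.fill_diagonal(block, v)
        cov[np.ix_(idx, idx)] = block
    return cov


def _sample_noise(
    config: SimulationConfig,
    rho_blocks: Dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw eps ~ N(0, block covariance) via the one-factor representation.

    An equicorrelated vector with variance v and correlation rho equals
    ``sqrt(v) * (sqrt(rho) * z0 + sqrt(1-rho) * z_g)`` with independent
    standard normals; this is exact and avoids factorizing the dense matrix.
    """
    n = config.n_samples
    eps = np.empty((config.n_total_genes, n))
    sd = math.sqrt(config.gene_variance)
    for name, idx in gene_blocks(config):
        rho = rho_blocks[name]
        shared = rng.standard_normal(n)
        own = rng.standard_normal((idx.size, n))
        eps[idx] = sd * (math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own)
    return eps


def simulate_expression(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the transcripts x samples expression matrix.

    Non-informative genes are ``mu + eps``; informative genes add
    ``beta * G`` for their one-to-one SNP.  With ``mu = log2(100)`` the
    output is non-negative in practice, as required for NMF input.
    """
    if genotypes.shape != (config.n_informative_genes, config.n_samples):
        raise ValueError(
            f"genotype matrix shape {genotypes.shape} does not match config "
            f"({config.n_informative_genes} SNPs x {config.n_samples} samples)"
        )
    if rng is None:
        rng = _substreams(config.seed)["noise"]
    if not truth.rho_blocks:
        truth.rho_blocks = draw_block_correlations(config)

    eps = _sample_noise(config, truth.rho_blocks, rng)
    values = config.baseline_log_mean + eps
    values[: config.n_informative_genes] += config.beta * genotypes.to_numpy()
    if (values < 0).any():
        warnings.warn("simulated expression contains negative values", stacklevel=2)
    gene_ids = _ids("gene", config.n_total_genes)
    return pd.DataFrame(values, index=gene_ids, columns=truth.sample_ids)


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Full reproducible bundle: expression, genotypes and ground truth.

    The single configured seed feeds independent sub-streams for genotypes,
    block-correlation draws and gene noise, so each component is
    reproducible on its own.
    """
    streams = _substreams(config.seed)
    genotypes, truth = simulate_genotypes(config, rng=streams["genotypes"])
    truth.rho_blocks = draw_block_correlations(config, rng=streams["rho"])
    expression = simulate_expression(config, genotypes, truth, rng=streams["noise"])
    return expression, genotypes, truth
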