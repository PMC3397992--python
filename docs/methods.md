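# Methods

This note records the models implemented in `endopheno`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical choices a maintainer would want to know.

## KL-divergence NMF

Given a non-negative matrix V (m transcripts × n samples) and rank k, the
model minimizes the generalized Kullback–Leibler divergence

    D(V ‖ WH) = Σᵢⱼ [ Vᵢⱼ log(Vᵢⱼ/(WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ],    0·log 0 := 0,

by the classical multiplicative updates

    H_aj ← H_aj · (Σᵢ W_ia Vᵢⱼ/(WH)ᵢⱼ) / Σᵢ W_ia
    W_ia ← W_ia · (Σⱼ H_aj Vᵢⱼ/(WH)ᵢⱼ) / Σⱼ H_aj ,

which never increase D. Numerical choices:

- **Initialization**: W, H entries i.i.d. uniform on (0, 1] scaled by
  mean(V)/k. Multiplicative updates rescale magnitudes within a few sweeps,
  so only the random pattern matters; the scale keeps early iterates away
  from the epsilon floor.
- **Epsilon floor** 1e-12 inside denominators and logarithms guards
  (WH)ᵢⱼ = 0; factors therefore stay strictly positive.
- **Stopping**: relative divergence change < `tol` (default 1e-6) for 10
  consecutive sweeps, or `max_iter` (default 2000). The divergence trace is
  stored and is monotone non-increasing up to 1e-10 relative noise.
- **Assignment**: sample j is labelled argmaxₐ H_aj (first index on ties).
  No W-column normalization is applied before assignment; a
  column-stochastic view of W is available for reporting only. A column of
  H that is identically zero cannot be assigned; it is labelled 0 and
  counted in `n_unassigned`.
- **Restarts**: multiplicative updates find local optima. `KLNMF.fit` is a
  single run (the unit the consensus machinery averages over);
  `KLNMF.fit_best` picks the lowest final divergence across seeded
  restarts and is used by the pipeline's single-fit stage (default 5
  restarts).

Useful identities exercised by the tests: at k = 1 the global optimum is
the independence model (row sums)(column sums)/total, and D is
1-homogeneous (D(cV‖cWH) = c·D(V‖WH)), which is why cluster assignments are
invariant to a global rescaling of V.

## Consensus clustering and rank selection

For each candidate k, `n_runs` independently seeded fits (default 50)
produce argmax-H partitions; the consensus matrix C is the mean of their
connectivity matrices. Stability is scored by the cophenetic correlation:
average-linkage hierarchical clustering on d = 1 − C, then the Pearson
correlation between the condensed (off-diagonal) entries of d and the
dendrogram's cophenetic distances. The diagonal is excluded because it is
constant and would inflate the correlation. If d is constant (a perfectly
stable single cluster) ρ is defined as 1 and a warning is emitted. k* is
the smallest k attaining the maximal ρ.

Caveat observed in testing: with extremely well-separated data, smaller
ranks can also be perfectly stable (every restart merges the same two
subtypes), giving ρ = 1 at k = 2 and k = 3 simultaneously; the
smallest-k tie-break then under-selects. This is a property of the
criterion, not of the implementation; the ρ table is always reported so
the plateau is visible.

## Informative-transcript selection

Each metagene's transcripts are ranked by their W coefficients (stable
sort; ties keep matrix order, and rankings are invariant to positive
column rescaling). For each t in the grid (default
{50, 100, 150, 200, 250, 300, 400, 800}) the union of per-metagene top-t
lists restricts V; a re-factorization at the same k uses a seed derived
deterministically from (base seed, t), so every row of the report is
individually reproducible. Agreement with the all-transcript reference
partition is measured by ARI and by the misclassification count after
Hungarian alignment of cluster labels on the contingency table. When the
union covers all transcripts the reference factors are reused — same data
and same seed policy imply the same fit, making the ARI = 1 row exact.
chosen_t is the smallest t with ARI ≥ 0.95 (configurable). A t whose union
has ≤ k transcripts cannot support a rank-k factorization and is skipped
with a warning. Metagene-specific sets drop any transcript present in two
or more top-chosen_t lists, so the sets are pairwise disjoint by
construction.

## PCA-K baseline

Genes are centred across samples (no variance standardization), the
centred matrix is decomposed by SVD, and samples are represented by their
projections on the leading right singular directions, ordered by singular
value. k-means (Lloyd, squared Euclidean) clusters the first k score
columns, keeping the best of 20 restarts by within-cluster sum of squares.
Retaining exactly k components makes the comparison with rank-k NMF
dimension-fair. Empty clusters are handled by scikit-learn's
farthest-point reseeding.

## The simulator

The generator emulates a bulk microarray cohort whose subtypes are driven
by common variants. Defaults are the reference study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| n_subtypes × samples_per_subtype | 3 × 80 | balanced cohort (n = 240) |
| informative_genes_per_subtype | 160 | one eQTL SNP per informative gene |
| pi_noninformative | 0.70 | fraction of genes with no subtype signal |
| baseline_maf / delta_maf | 0.1 / scenario | HWE dosage Bin(2, p); p = 0.1 + Δ in the gene's own subtype |
| beta | scenario | additive SNP effect on log2 expression |
| baseline_log_mean | log2(100) ≈ 6.644 | shared gene baseline |
| gene_variance | 0.3 | marginal noise variance per gene |
| corr_range | (0.4, 0.6) | per-block equicorrelation, drawn once per block |

Total gene count is 3·160/(1 − π) rounded to the nearest integer, so at
π = 0.7 exactly 1120 non-informative genes join the 480 informative ones.
The noise covariance is block-diagonal: one equicorrelated block per
subtype's informative genes plus the non-informative genes split into
n_subtypes near-equal blocks (their block membership is a modelling choice;
nothing downstream depends on it beyond the block sizes). Each block's ρ is
drawn once, uniform on corr_range, and recorded in the ground truth.
Sampling uses the exact one-factor representation of an equicorrelated
normal (√ρ·shared + √(1−ρ)·idiosyncratic), avoiding dense Cholesky
factors. A single seed feeds three independent sub-streams (genotypes, ρ
draws, noise), so each component is reproducible in isolation.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs, missing data, batch effects, gene-specific baselines or variances,
and any correlation between blocks. Passing tests therefore demonstrate
recovery of block-structured, variant-driven subtypes under homoscedastic
correlated noise — not robustness to the full messiness of real microarray
data.

### What the noise model implies for purity

The equicorrelated factor of each block lies exactly along that block's
mean-expression direction — the same direction that carries the subtype
signal (mean shift 2βΔ). The factor contributes irreducible noise of sd
√(0.3·ρ) ≈ 0.39 there, so at Δ = 0.2 and β = 0.5 the signal-to-noise
ratio in the informative block means is ≈ 0.5, and even an oracle given
the true block structure attains mean purity only ≈ 0.44 (≈ 0.42/0.53 at
β = 0.3/0.8). Unsupervised NMF and PCA-K sit slightly below that, near
0.38–0.40; purity climbs steeply once 2βΔ exceeds the factor sd
(Δ ≈ 0.5 at β = 0.8) and both methods approach 1 by Δ = 0.9. In this
implementation the PCA-K baseline (k retained components, 20 k-means
restarts) is a strong competitor: it matches or slightly exceeds
single-run NMF purity across the sweep, and consensus-NMF labels narrow
but do not reverse the gap. The sweep reports both methods with standard
errors so the comparison is explicit.

## Simulation sweep

`run_scenario` draws a fresh dataset per replicate (seeds derived from a
per-scenario SeedSequence), fits one seeded NMF run (no consensus) and
PCA-K at the true k, and scores purity against the planted labels;
`run_sweep` aggregates means and standard errors over a scenario grid.
Defaults: 200 replicates per scenario for library use; the acceptance
surfaces use 100 (the experiment's reference precision at desk scale).
Within the sweep, NMF uses max_iter = 300 and tol = 1e-5: purity at these
settings is indistinguishable from runs at max_iter = 800 / tol = 1e-6
(checked at Δ = 0.2 and 0.5), and the sweep's cost is dominated by these
fits. Consensus-mode clustering remains available through the consensus
module for users who want Brunet-style stabilized labels at ~n_runs× cost.

A caveat of the single-run arm: at strong separation (Δ = 0.9, β = 0.8) the
per-replicate NMF purity is bimodal — most runs recover the subtypes
(≈ 0.97–1.0) but a minority collapse into a local optimum that merges two
subtypes (≈ 0.6), dragging the mean to ≈ 0.89–0.98 depending on the seed
batch. Final divergence does not reliably distinguish collapsed from good
solutions, so best-of-restarts selection by divergence does not cure it;
consensus labels do (mean ≈ 0.98), at n_runs× cost. The sweep reports
standard errors so the instability is visible in the output.

## Preprocessing

Fixed stage order: missing-fraction filter (> 30 % missing dropped) →
log2 (non-positive values are an error, with offending entries listed) →
mean/variance percentile filter → per-transcript mean imputation →
(genotypes) MAF filter (MAF = min(p, 1−p) with p = Σcodes/2n; drop
MAF < 0.10). Every stage appends its before/after counts to a
`FilterReport`, and each filter is idempotent on its own output.

"Mean expression in the upper 70th percentile" is genuinely ambiguous.
Both readings are implemented behind one keyword: `top-fraction` (default)
keeps the top P % of transcripts (statistic ≥ the (100−P)th percentile);
`above-percentile` keeps transcripts at or above the Pth percentile.
Percentiles use linear interpolation and ties are kept (≥); a percentile
of 0 disables that component of the filter.

## Downstream analyses

- **Differential expression**: per-transcript two-sample t-test,
  pooled-variance by default to stay algebraically consistent with
  Cohen's d (t = d·√(n₁n₂/(n₁+n₂))); Welch via `equal_var=False`. The
  default significance threshold is p < 1e-4 with no multiple-testing
  correction, matching the procedure's exploratory design; a
  Benjamini–Hochberg step can be applied downstream by the caller.
  Degenerate transcripts (zero variance in both groups) get p = 1 when the
  means agree and p = 0 otherwise.
- **Permutation validation**: case samples are randomly regrouped into
  pseudo-subtypes of the observed sizes; per permutation, Cohen's d
  against controls is computed per transcript, and the per-permutation
  empirical distributions are combined by averaging each of 999 equally
  spaced quantiles (grid i/1000). Structured subtypes show wider effect-
  size spread than the combined null; random regroupings reproduce the
  pooled-cases curve up to the sampling-width difference implied by the
  smaller group sizes.
- **MGL-QTL mapping**: each H row is regressed on each SNP's dosage
  (simple OLS; two-sided p from t with n−2 df, vectorized across SNPs and
  cross-checked against statsmodels). Constant-dosage SNPs are skipped
  with a warning. The u-allele is the coded (minor) allele when the slope
  is positive, the major allele otherwise; reversing the dosage coding
  flips both the slope sign and the u-allele. Subtype summaries report,
  per MGL-QTL set, the mean u-allele frequency within each subtype. No
  overlapping-SNP exclusion is applied before QTL mapping; the CLI prints
  a note to that effect.

## Known limitations

- Multiplicative-update NMF converges slowly near flat optima; on
  offset-dominated matrices (all values ≈ μ) the factorization spends most
  of its capacity on the shared background, and cluster assignment relies
  on small differences between H rows. Consensus averaging or
  `fit_best` mitigates seed sensitivity but not the information limit
  described above.
- The cophenetic criterion can tie at ρ = 1 across ranks on
  near-noiseless data (see above); inspect the full ρ table.
- `u_allele_frequencies` assumes the dosage coding's minor allele is the
  u-allele candidate; for SNPs whose sample MAF exceeds 0.5 the
  minor/major terminology follows the coding, not the realized frequency.
- The pipeline persists every stage but does not checkpoint/resume;
  stages rerun from scratch on every invocation.
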