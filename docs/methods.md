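# Methods

This note documents the models, the parameter choices that matter, the
synthetic cohort the test-suite runs on, and the known limitations. Nothing
stated here goes beyond what the package's tests and `scripts/acceptance.py`
themselves compute.

## Pathway-guided factorization

The core decomposition of the z-scored expression matrix `X` (genes g ×
samples s) is

    min_{Z≥0, B, U≥0}  ‖X − ZB‖²_F + λ₁‖Z − CU‖²_F + λ₂‖B‖²_F + λ₃‖U‖₁

where `C` (g × p) is the binary gene-by-gene-set prior and `U` (p × k) picks
a sparse nonnegative pathway combination per latent variable (LV). The solver
is block coordinate minimization, with each block solved exactly:

- `B ← (ZᵀZ + λ₂I)⁻¹ZᵀX` (ridge least squares, closed form);
- `Z`: one cyclic sweep of exact column minimizations
  `Z_j ← max(0, (XBᵀ_j + λ₁(CU)_j − Σ_{l≠j} Z_l G_{lj}) / (G_jj + λ₁))` with
  `G = BBᵀ` — an exact nonnegative minimizer per column, unlike the common
  "solve then clip" heuristic, which can increase the objective;
- `U`: cyclic coordinate updates with nonnegative soft-thresholding at
  `λ₃ / (2λ₁)`.

Because every block step is an exact minimization over its block, the
objective is non-increasing after each full cycle; the invariant is asserted
along `objective_trace` in the tests. Iteration stops when the relative
Frobenius change of `B` falls below `tol = 5e-3` or after 350 iterations
(bounded cost; the `converged` flag is recorded in the model manifest).

**Initialization.** `Z` from the top-k left singular vectors of `X` (signs
fixed so each column sums nonnegative, then truncated at zero), `B` from the
corresponding `sΣVᵀ` rows. Deterministic, so the whole fit is deterministic.

**Automatic penalties.** When not supplied, `λ₂ = s_{k+1}` — the first
singular value *not* retained by the model, i.e. the noise floor — with
`λ₁ = λ₂/2`, floored at `1e-6·s₁` for rank-deficient input. The scale
matters twice over. A rank-one component of strength `s` survives the two
quadratic penalties only if `s > √(λ₁λ₂)`, and each survivor is shrunk by
about `√(λ₁λ₂)`; penalties at the signal scale (`s_k` or `s_k²`) therefore
either discard everything or bias every retained component by a
signal-sized amount, and they also inflate the ridge mixing in the `B` step,
which leaks activity between modules. Penalties at the noise edge shrink
each retained component by less than the noise itself and vanish on
noise-free input, where reconstruction is then essentially exact (relative
error ≈ 0.02 on a rank-k cohort, measured in the tests). `λ₃` is tuned by
geometric bisection over short refits (≤ 6 refits of ≤ 40 iterations) so the
fraction of LVs with at least one nonzero pathway coefficient is closest to
the target `frac` (default 0.7), then the final model is refit to full
convergence.

**Component count.** Permutation parallel analysis: each gene row is
permuted independently (20 permutations), and k is the length of the leading
run of observed singular values above the rank-matched 95th-percentile null
singular values. On the default synthetic cohort this recovers the planted
k = 20 exactly (recomputed by the acceptance script).

**Pathway alignment.** One fifth of each prior set's members (rounded) is
masked from `C` before fitting; after fitting, every (LV, set) pair with a
nonzero `U` entry is scored by the Mann–Whitney AUC of the LV's raw
(nonnegative) loadings for held-out members versus all non-members, with the
one-sided normal-approximation p-value and BH correction across all scored
pairs (table-wide, since a per-LV scope is equally defensible but less
powerful at small k). Pairs with fewer than two held-out members are
skipped. The hold-out is reconstructed deterministically from (C, fraction,
seed), so alignment can be scored in a separate process from the fit.

## Differential module activity

Per-LV two-sided Wilcoxon rank-sum test of T21 vs D21 activities: exact
distribution when both groups have ≤ 25 samples and no ties, otherwise the
normal approximation with continuity and tie correction. BH correction
across LVs. The activity matrix is standardized and signed, so a fold change
is ill-defined; the reported effect is the difference of group means in
standardized activity units (convention recorded in the output metadata),
with the conventional 0.25 threshold applied to its absolute value for the
"top SGM" flag on top of the FDR < 0.05 gate.

The chromosome-21 representation test assigns each gene to the SGM group if
it is in the top 5% by |loading| of any SGM, and to the non-SGM group if it
is a top gene of any non-SGM module *and not already in the SGM group* (the
groups must partition for a 2×2 table; SGM membership takes precedence).
The two-sided Fisher exact p-value comes from hypergeometric enumeration.

## Over-representation analysis

Query = top ⌈0.05·g⌉ genes by |loading| (ceiling, boundary ties broken by
gene identifier so results are independent of input row order); universe =
all quantified genes; statistic = one-sided hypergeometric upper tail
P(X ≥ overlap); BH across all (LV, set) pairs of a run. Sets with no member
in the universe are skipped with a log record.

## GLS enrichment regression

TWAS p-values are mapped to nonnegative normal-scale scores
`y = Φ⁻¹(1 − p/2)` (p clipped below at 1e-300); a linear model on p-values
directly would be meaningless, and the probit magnitude is the monotone
transform under which null scores are half-normal. For module l, the
indicator `s_l` flags the top ⌈0.01·g⌉ genes by |loading|. The fit is

    y = β₀ + β_s s_l (+ covariates) + ε,  ε ~ (0, σ²Σ)

estimated by Cholesky whitening; the one-sided p-value is the upper t tail
on β_s with g − rank(D) degrees of freedom (enrichment = positive
coefficient, matching the question of whether a module's core genes are
*more* trait-associated than background). Gene-level covariates are
accepted but default to none.

Σ is a gene–gene correlation matrix, shrunken as `(1−τ)Σ + τI` with
τ = 0.05, raised analytically (from the smallest eigenvalue) whenever needed
to keep the minimum eigenvalue above 1e-8 — empirical correlation matrices
from finite cohorts are rank-deficient. By default the pipeline derives Σ
from the normalized expression matrix; a precomputed matrix can be supplied
instead (`sigma` in the pipeline config, `--sigma` on the CLI). The two
choices answer slightly different questions: the expression-derived Σ
discounts co-expressed genes — by design, since co-expression is the main
confounder on real TWAS scores — which also means it discounts planted
signals that do not follow the co-expression structure. The synthetic
truth therefore declares its own `Sigma_true` (the block correlation of the
simulated residuals) as the matrix the GLS stage consumes in truth-aware
evaluations, and the acceptance runs pass it through the override.

Why GLS at all: under a block-correlated null (ρ = 0.3, blocks of 10 genes,
2,000 genes) with the indicator selecting whole blocks — the realistic case,
since a module's top genes are co-expressed — the one-sided OLS test
rejects at ≈ 0.19 instead of 0.05, while GLS with the true Σ stays at
≈ 0.05 (1,000 replicates, recomputed by the acceptance script and asserted
in the tests).

BH correction is applied across the full (module, trait) grid with an
FDR < 0.1 flag. Traits scoring fewer than 100 model genes are skipped;
genes without a score are dropped pairwise; both with log records.

## Comorbidity classification

Among T21 samples only (case/control status is undefined for euploid
controls), each (module, comorbidity) pair with ≥ 5 cases and ≥ 5 controls
is scored by ROC AUC (Mann–Whitney normalization, ties 0.5) and balanced
mAPS: average precision recomputed over 50 subsamples of the negative class
matched in size to the positives, then averaged (mean and Monte-Carlo SD are
both reported; when controls are fewer than cases all controls are used each
iteration, logged). A pair "passes" when AUC > 0.65 and mAPS > 0.65; the
minimum class size is exposed as configuration rather than hard-coded as a
third criterion. Each pair draws its subsamples from an independent stream
derived from the master seed, so a single pair can be re-run in isolation
and reproduce exactly. The top-quartile test dichotomizes samples at the
empirical 75th percentile of activity and applies the one-sided Fisher
exact test for case over-representation.

## The synthetic cohort

Defaults (chosen once as a desk-scale proxy for a whole-blood trisomy
cohort of roughly 36k genes × 400 samples, and held fixed):

| parameter | default | meaning |
|---|---|---|
| genes / samples | 2,000 / 300 T21 + 100 D21 | desk-scale cohort |
| modules (k_true) | 20 | planted loading/activity pairs |
| prior sets | 50, sizes 20–60 | random membership |
| frac_aligned | 0.75 | modules given a matching prior set |
| noise_sd_loadings | 0.1 | off-pathway loading noise (before truncation at 0) |
| noise_sd_expression | 0.3 | residual noise, block-correlated |
| corr blocks / ρ | 10 genes / 0.3 | compound-symmetric residual correlation |
| sgm_indices / effect | (0,1,2) / 1.0 SD | karyotype activity shifts |
| trait plants | 2 at effect 1.5 (+2 null traits) | additive inflation of top-1% genes' half-normal score magnitude |
| comorbidity plants | 1 at slope 3, intercept 0 (+1 null) | logistic labels from one module's activity, T21 only |
| frac_chr21 | 0.02 | genes annotated to chromosome 21 |

Construction: `Z_true = max(0, C·U_true + noise)` with one unit-weight
pathway per aligned module; `B_true` rows standard normal with the karyotype
shift added to T21 columns of the shifted rows; `X = Z_true·B_true + E` with
`E` block-compound-symmetric. Trait scores are |N(0,1)| magnitudes with the
enrichment effect *added* to the top-1% genes of the planted module
(additive inflation keeps the enrichment monotone in the effect size);
p = 2(1 − Φ(|z|)). Null traits and null comorbidities are represented as
plants with zero effect/slope and are excluded from the planted-truth sets.
Everything is drawn from one `numpy` generator seeded by the config, so
identical configs give bit-identical cohorts.

What the generator does **not** emulate: library-size and count-noise
structure (TPM/UMI), realistic LD or co-expression topology (residual
correlation is block-constant), gene-length or GC effects, covariates such
as age and sex, and TWAS score correlation induced by LD. Passing tests
therefore demonstrate that the pipeline recovers the statistical structure
it models, not that it is robust to every artifact of real cohorts.

## Truth-aware evaluation

Fitted modules are compared to planted ones two ways. *Recovery* uses
one-to-one assignment (Hungarian algorithm on absolute loading
correlations): at expression noise 0.3 the mean matched |correlation| is
≈ 0.89–0.90 across seeds. *False-positive accounting* tags each fitted
module with its argmax-correlated true module: a flagged module, link or
classifier counts as a false positive only when its tag is a non-planted
module. The distinction matters because the factorization occasionally
splits a planted module across two fitted LVs; both halves genuinely carry
planted signal, and counting the second as a "false positive" would
misstate specificity.

## Numerical and degenerate-input conventions

- Constant gene rows z-score to all-zero (logged), never NaN.
- Constant fitted loading columns / activity rows are excluded from
  post-hoc standardization (left as zeros).
- All-zero loading columns fall back to lexicographic gene order in
  indicator construction, with a warning.
- Fisher tests with a zero margin return p = 1 (scipy convention).
- BH on an empty vector returns an empty vector; single p-values are
  returned unchanged.
- Ties: Mann–Whitney statistics count ties as 0.5 everywhere (alignment
  AUC, ROC AUC, Wilcoxon); top-gene selections break ties by gene
  identifier.
- Seeds: one master seed per pipeline run fans out into per-stage streams
  via `SeedSequence`, and per-(module, comorbidity) subsampling streams are
  derived the same way.

## Problem sizes used by the shipped checks

The test-suite and acceptance script run the full pipeline at the default
2,000 × 400 cohort (5 seeds for the planted-recovery and global-null
properties), the GLS calibration at 2,000 genes × 1,000 replicates, and the
oracle comparisons at 500–1,000 random instances each; unit tests use a
300-gene cohort. These sizes were chosen so the whole suite completes in a
few minutes on one CPU while every statistical bound retains its power.

## Known limitations

- The factorization is a local optimizer with a deterministic SVD warm
  start; it does not attempt multiple restarts, and exact numerical
  agreement with any other implementation of pathway-guided factorization
  is out of scope.
- Module splitting (one planted module recovered as two correlated LVs)
  occurs occasionally and is handled at evaluation time, not prevented.
- The GLS stage treats Σ as known; uncertainty in an estimated correlation
  matrix is not propagated.
- Differential activity is unadjusted for covariates.
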