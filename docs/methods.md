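# Methods

`causalde` estimates per-gene causal log fold changes (LFCs) from count-based
omics data — bulk, pseudo-bulk or single-cell — when treatment assignment may
depend on unmeasured confounders. It combines three ingredients: a
negative-binomial generalized factor model that estimates latent confounders
from the count matrix itself; doubly robust AIPW estimation of potential
outcomes with influence-function inference; and multiple-testing control by
FDR (Benjamini–Hochberg) and FDX (Lehmann–Romano). A replicated-simulation
benchmark scores error-rate control and confounder recovery.

## Model

Counts `Y_ij` (observation i, gene j) are negative-binomial with
per-gene dispersion `phi_j` (variance `mu + mu^2/phi`) and mean

    E[Y_ij] = s_i * m_ij,        log m_ij = x~_i' b_j + u_i' gamma_j,

where `s_i` are size factors, `x~_i = (1, x_i, a_i)` stacks an intercept,
observed covariates and the treatment indicator(s), and `u_i` are `r` latent
confounder scores with gene loadings `gamma_j`. The exponential-family form of
the NB (natural parameter `theta = log(m/(m+phi))`, log-partition
`A(theta) = -phi log(1-e^theta)`) underlies the likelihood computations; the
*regression surface* uses the log link rather than the canonical link. This is
a deliberate choice: the canonical link saturates (`theta < 0` corresponds to
a finite-mean boundary), which makes additive latent structure on the theta
scale numerically fragile and biologically odd (effects amplify explosively
near the boundary), whereas multiplicative (log-scale) structure is the
standard model for expression data and matches the downstream outcome GLMs.

### Estimation of the factor model

Alternating blocks of Fisher-scoring Newton updates, batched across genes
(update `(b_j, gamma_j)` rows given `U`) and across observations (update
`u_i` given loadings), each with per-unit step halving so the joint
likelihood never decreases. Initialization: per-gene GLM at `r = 0`, SVD of
its Pearson residuals, latent scores started at the top-`r` left singular
vectors (unit scale) with zero loadings — starting loadings at zero lets the
first gene block line-search into the basin and empirically reaches the same
optimum as oracle initialization, where seeding both scores and loadings
from the residual SVD often does not.

**Row intercepts.** A free per-observation intercept `alpha_i` (loadings
pinned at 1) is fit alongside the factors, as in GLM-PCA. At realistic
sparsity, plug-in size factors carry substantial error which otherwise
appears as a rank-1 "phantom factor" with near-constant loadings: it
contaminates the latent scores and inflates rank selection by one. After
convergence `alpha` is folded into effective size factors
`s_i <- s_i * exp(alpha_i)` (renormalized to mean 1, with the shift absorbed
exactly into the gene intercepts), which the causal stage reuses.

**Identifiability and the augmentation step.** The decomposition is exactly
flat along `(B, U) -> (B + Gamma D', U - X~ D)`: only the span of `[X~, U]`
is likelihood-identified. We report the representative with `U` orthogonal
to `X~` and `U'U` diagonal decreasing. That representative, however, assigns
any treatment-aligned confounder component to the treatment column of `B` as
a *dense* shift across genes — exactly the component needed to deconfound.
Because true treatment effects are sparse while this shift is linear in the
loadings, a Huber-robust regression of the fitted treatment column on
`[1, Gamma]` recovers the per-treatment latent shift `d`, and

    U_causal = U_perp + A d'

is the confounder estimate handed to the causal stage. The same flatness
argument motivates a second, effect-level correction (below).

**Dispersions.** Two-stage: method-of-moments `phi = mean^2/(var - mean)` on
adjusted counts, then a vectorized-bisection NB MLE per gene holding fitted
means fixed — first at the `r = 0` GLM means, and refined once at the
converged factor-model means (latent variance otherwise inflates apparent
overdispersion several-fold). Dispersions are held fixed during the
alternation; joint updates destabilize the block likelihood.

**Rank selection** minimizes `JIC(r) = -2 loglik(r) + nu * r * (n+p) *
log(min(n,p))`, with the full-pmf log-likelihood and a penalty constant
`nu = 0.5` calibrated once on pilot data: per-rank overfit gains on
pure-noise NB matrices are ~0.12 penalty units while the weakest realistic
planted factor contributes ~0.9 units, so 0.5 separates them with margin in
both directions. All candidate ranks share one dispersion vector taken from
a prefit at the largest candidate rank (a crude `r = 0` dispersion estimate
drowns weak factors; per-rank refits would let dispersion overfitting leak
into the criterion).

## Causal estimation

For gene j the estimand is `tau_j = log(E[Y_j(1)] / E[Y_j(0)])` on the
size-factor-adjusted scale. With `W = [X, U_causal]`:

- **Outcome models**: per-gene NB GLMs of `Y_j` on `(W, A)`, log link,
  offset `log s`, dispersions from the factor fit; batched IRLS with ridge
  stabilization for non-converging genes.
- **Propensity**: logistic regression on `W` (in sample; parametric
  nuisances are Donsker) or a cross-fitted random forest (5 folds; defaults
  min 10 samples/leaf, min 20 to split, sqrt features, balanced class
  weights, cost-complexity pruning 0.02; optional grid search over 200–1000
  trees, depth {3,5,7}, per-tree subsample {0.4,0.6,0.8,1.0}). Probabilities
  are clipped to [0.01, 0.99]; the clipped fraction is reported as an
  overlap diagnostic.
- **AIPW imputation**: `Yhat(a) = mu_a(W) + 1{A=a}/pi_a(W) * (Y - mu_a(W))`
  elementwise, consistent when either nuisance model is correct.
- **Effects and inference**: `tau_hat_j = log(mean Yhat_j(1) / mean
  Yhat_j(0))`; influence values by the delta method,
  `eta_ij = (Yhat_ij(1)-psi1)/psi1 - (Yhat_ij(0)-psi0)/psi0`, mean zero per
  gene by construction. The default standard error is
  `sigma^2 = Var(eta)/n`; a `paper_formula` mode retains the alternative
  printed scaling `sqrt(n)/(n-1) * sum(eta^2)` verbatim for audit — it is
  dimensionally inconsistent with the sqrt(n)-rate expansion the influence
  function satisfies, and the Monte-Carlo coverage tests (95% CIs covering
  0.93–0.97 under correct specification) arbitrate in favor of the standard
  form. `T = tau_hat/sigma_hat` is referred to the standard normal.

Two calibration safeguards address error in the *estimated* confounders,
which propagates identically into both nuisance models (double robustness
cannot repair it):

1. **Effect-level debias** — Huber-robust regression of `tau_hat` on
   `[1, Gamma_hat]`, subtracting the fitted dense component. Residual
   confounding from score error is approximately linear in the loadings and
   shared across genes; true effects are sparse and act as outliers. This is
   the standard second-stage correction of factor-based confounder
   adjustment.
2. **Empirical-null recalibration** — with mostly-null genes, the median
   absolute z-score (MAD/0.6745) estimates the realized null scale; when it
   exceeds 1 it is folded into `sigma_hat` (never deflating reported
   uncertainty), so `T = tau/sigma` stays exact. This absorbs the
   second-order variance contribution of confounder-estimation noise and is
   the classic large-scale-inference empirical-null device.

Both are on by default and can be disabled (`debias`, `empirical_null`).

**Multiple testing**: BH step-up q-values with rejection at FDR alpha
(default 0.1), and a Lehmann–Romano step-down controlling
`P(FDP > gamma) <= alpha` with thresholds
`alpha_i = (floor(gamma i)+1) alpha / (m + floor(gamma i) + 1 - i)`
(defaults gamma 0.1, alpha 0.05). FDX rejections are conservative relative
to BH in practice.

**Multi-treatment designs** fit the factor model once with one-hot treatment
columns and then run each one-vs-control contrast through the binary AIPW
pipeline on its subset, reusing the shared confounder rows; propensities are
binary per contrast, matching the one-vs-control estimand.

## Size factors

Defaults to median-of-ratios with the classic all-positive-gene reference;
when sparsity leaves fewer than 50 such genes, a poscounts-style reference
(genes nonzero in ≥ 50% of observations, per-cell median ratio over that
cell's nonzero reference genes) replaces it. Library size is available but
never the silent fallback: it is a post-treatment quantity, and with ~10% DE
genes it measurably leaks treatment effect into the adjusted scale of every
null gene. Final depth correction comes from the factor model's row
intercepts (above).

## Downstream analyses

Counterfactual distribution summaries report quantiles (5/25/50/75/95%) and
means of `log(Yhat(a) + 1)` per arm. Conditional effects `tau_j(v)` smooth
each arm of the imputed potential outcomes against a covariate (LOESS-style:
tricube weights, local degree 1, span 0.75, 50 grid points) and take the
log-ratio of the arm smooths — smoothing arms rather than per-observation
pseudo-effects avoids logs of non-positive imputed values. 95% bands are
percentile bootstrap over observations (200 resamples), united with the
point estimate so the band always contains it; grid points with fewer than
5 observations in the smoothing window, or a non-positive smoothed arm,
return NaN. A near-constant covariate degenerates exactly to the marginal
estimate.

## Synthetic data

The generator mirrors the benchmark's study conditions: n = 100–5000
observations (default 500), ~2000 genes, 1–2 observed covariates, 4 latent
confounders, 10% DE genes with |LFC| uniform on [0.5, 1.5] (signs balanced).
Latent rows come from a mixture of 4 Gaussians (centers sd 3.5, within-group
sd 0.6 per dimension) — well-separated, cell-type-like groups, calibrated so
that *oracle* metrics on the ground truth sit in the intended regime
(k-means on true scores: ARI ≈ 0.96; silhouette of raw control counts:
ASW ≈ 0.76 rescaled). Confounding enters assignment as
`logit P(A=1) = strength * z(U) + 0.3 * sum(X)` with `z` the standardized
mean latent score; `strength = 1` is the moderate default (exposed grid
{0, 0.5, 1, 2}). Gene means are assembled multiplicatively
(`log m = log m0 + X bx + A lfc + U gamma`, baseline means log-normal with
median 0.5 and log-sd 1, loadings N(0, 0.25^2), covariate effects
N(0, 0.15^2)); counts are NB with dispersions log-uniform on [1, 10] and
log-normal size factors (CV 0.3, mean 1). A single-cell mode doubles the
size-factor CV, halves baseline means and dispersions. On this scale the
planted treatment coefficient *is* the estimand; `true_tau` is nevertheless
computed exactly by counterfactual averaging of the (clipped) mean matrices,
so null genes are exactly null.

What the generator does not emulate: zero-inflation beyond NB sparsity,
gene–gene correlation beyond the latent factors, batch structure in the
size factors, cell-type proportions varying with treatment, and real
library-size distributions. Passing benchmarks therefore demonstrates
correctness of the estimation machinery under its stated assumptions, not
performance on any particular real dataset.

## Benchmark metrics

Per simulated replicate: FPR and TPR of the per-gene test at nominal raw-p
level 0.1 (q-value thresholds available as an option); ARI between k-means
clusters (k = true group count, 10 restarts, fixed seed) of the estimated
confounder scores and the true groups; ASW of the true groups in the imputed
control matrix `Yhat(0)` — log1p transform, top-20 PCs, Euclidean
silhouette, rescaled from [-1,1] to [0,1] via (s+1)/2. The log1p transform
is a deliberate choice: raw count-scale distances are dominated by a handful
of high-mean genes. The replicated harness (`run_benchmark`) emits a tidy
table of config x replicate x metric and never mutates its input configs.

## Problem sizes and numerical choices

Default benchmark scale is 20 replicates of n = 500 x p = 2000 with fitted
ranks {2, 4, 6}; one pipeline run takes ~10 s on a single core (batched
Newton blocks are O(n p q^2) per iteration via BLAS matmuls). Optimizer
defaults: outer tolerance 1e-4 (relative joint log-likelihood, 2 consecutive
iterations), max 100 outer iterations, 2 Newton steps per block, 30 step
halvings; means clipped to [1e-8, 1e6]; dispersions clamped to [0.01, 100]
(zero-variance genes to the upper bound). Genes with a non-positive imputed
arm mean report NaN effects rather than pseudo-counted values; pseudo-counts
are reserved for display.

## Known limitations

- Confounder-estimation error propagates into effect estimates; the debias
  and empirical-null steps remove its first-order and scale effects, but
  replicates with weakly identified latent structure remain noisier and the
  calibration then trades some power for error control.
- FDX control uses the Lehmann–Romano bound, which is conservative under
  positive dependence of the tests.
- In-sample nuisance fitting relies on parametric (Donsker) nuisances; the
  random-forest propensity is cross-fitted, but the NB outcome models are
  not.
- The natural-parameter exponential-family form is used for likelihood
  evaluation, while latent structure is modeled on the log-mean scale; data
  whose confounding acts additively on the canonical scale would be
  mildly misspecified (the fit then targets the best log-scale projection).
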