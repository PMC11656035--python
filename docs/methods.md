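# Methods

## The fine-mapping model

A GWAS locus contains p variants with z-scores `z_j = beta_j / se_j` from
per-variant logistic regression, and an LD matrix `R` (Pearson correlation
of dosages over the same individuals — in-sample LD; using mismatched
reference-panel LD is a known source of convergence failure for
summary-statistic fine-mappers, so this package computes LD from the
analysis sample whenever genotypes are available).

The standardized multi-variant effect vector `b` is modelled as a sum of L
single-effect vectors, `b = sum_l b_l`, where each `b_l` has exactly one
nonzero coordinate, chosen from a categorical prior (uniform over the locus
by default) with a normal prior `N(0, s0_l)` on the nonzero value. On
residualized z-scores the single effect regression (SER) is conjugate:

- log Bayes factor per variant:
  `lbf_j = -1/2 log(1 + s0) + 1/2 z_j^2 s0/(1 + s0)`
- inclusion probabilities: `alpha_j ∝ pi_j exp(lbf_j)`
  (computed with the max-shift for numerical stability)
- posterior moments given inclusion: `mu1_j = z_j s0/(1+s0)`,
  posterior variance `s0/(1+s0)`.

Fitting is iterative Bayesian stepwise selection: within each sweep,
effect l is refitted to `z - R @ sum_{k != l} (alpha_k * mu1_k)`, in order
l = 1..L. Because the SER posterior is exact, every update is an exact
coordinate maximisation of the variational objective, which therefore
increases monotonically; the objective is tracked per sweep (up to an
additive constant — `y'y` is not identified from z-scores, only objective
*differences* are meaningful). Convergence is declared when the largest
absolute PIP change between sweeps drops below `tol = 1e-3` (PIPs are what
credible sets depend on); `max_iter = 100`.

### Prior variance estimation

Each effect's prior variance is chosen per update by maximising the SER log
Bayes factor over a fixed grid: 0 plus 15 log-spaced values in
[1e-3, 1e2] (z-score scale, covering GWAS-scale standardized effects).
Including 0 lets superfluous effects switch off: for a null residual the
best achievable `lbf_j` cannot overcome the `log p` Occam penalty implicit
in `log sum_j pi_j exp(lbf_j)`, so the effect reverts to `s0 = 0` and is
excluded from PIPs and credible sets. Because the grid is fixed across
sweeps, the chosen value always weakly dominates the previous one and
objective monotonicity is preserved.

### Credible sets

For each non-null effect, variants are ranked by `alpha` (ties broken
toward the lower index for determinism) and the shortest prefix whose sum
reaches the coverage level is taken. Defaults: coverage 0.95; purity floor
0.5 on the minimum absolute pairwise LD among members (singletons have
purity 1), evaluated on the repaired LD matrix — the matrix the model saw.
Without a purity floor, a null effect forced to 95% coverage would emit a
giant diffuse set; the floor is what makes "no credible set" a reportable
outcome. Exact duplicate member sets are collapsed, keeping the higher
achieved coverage. A small table of per-locus coverage overrides (0.6-0.8
at five loci that otherwise produce no nonempty set) ships as package data
and is applied by `locus_config_for`.

## Association statistics

Per-variant logistic regression maximises the Bernoulli likelihood with
linear predictor `intercept + dosage (+ covariates)` by Newton-Raphson to
gradient norm < 1e-8 (at most 50 iterations). Without covariates all
variants are updated simultaneously via closed-form 2x2 solves, which keeps
a 300-variant locus at ~1000 individuals around a millisecond per
iteration. `se` is the observed-information standard error; `p` the
two-sided normal tail of `z`. Variants that are monomorphic, fail to
converge, or show separation (|beta| > 15) are excluded with a warning
rather than crashing the locus. Variants with MAF <= 1e-4 are filtered
(strict inequality), subsetting the LD matrix in lockstep.

### Positive-definite repair

`repair_psd` eigendecomposes `R`, floors eigenvalues at `eps = 1e-4`,
reconstructs, and rescales to unit diagonal. Inputs already compliant
(minimum eigenvalue >= eps) pass through unchanged. After a genuine repair
the diagonal rescaling can leave the minimum eigenvalue marginally below
eps, so the operation is idempotent only up to ~1e-6 entrywise — inherent
to the floor-then-rescale recipe, and harmless since any positive floor
suffices for the Cholesky factorisation the fitter needs.

## The synthetic panel and disease models

`generate_haplotype_panel` produces binary haplotypes by thresholding a
latent stationary AR(1) Gaussian per block (lag-one correlation 0.9 by
default, 6 blocks of 50 variants) at the quantile of a per-variant target
frequency drawn uniformly from [0.05, 0.5]. This reproduces the two
features the downstream machinery cares about — exponentially decaying
within-block LD and cross-block independence — with ~1.3 kb spacing
(0.4 Mb / 300 variants, a realistic density for a dense fine-mapping
locus).

What it does **not** share with real haplotype panels: thresholding
attenuates correlation, capping the binary-scale LD of an adjacent
equal-MAF pair at `(2/pi) arcsin(0.9) ≈ 0.71` (lower for unequal MAFs, and
≈ 0.5 at lag 3). Real panels routinely contain near-perfectly correlated
variant pairs (|r| > 0.95). Consequently the default panel exercises the
weak-to-moderate LD regime; scenarios that depend on near-perfect LD
(e.g. two causal variants merging into a single credible set) require
raising `within_block_corr` toward 1 and narrowing the MAF range, as the
high-LD merging test does (`within_block_corr = 0.999`, MAF in [0.35, 0.5],
attaining |r| ≈ 0.96). Passing tests on the default panel therefore
demonstrate correct behaviour under moderate LD; the merging behaviour
under extreme LD is demonstrated separately.

Two disease mechanisms:

- **Genotypic relative risks** (`simulate_case_control_grr`): penetrance
  `f0 * prod_k GRR_k(g_k)` with GRR defaults (2, 4) for one/two copies,
  multiplicative across causal variants (standard retrospective-sampling
  practice). `f0` is fixed by a configurable population prevalence
  (default 0.10, which keeps penetrances below 1 with GRR 4 at common
  MAFs) through the *exact* causal-genotype distribution implied by random
  mating on the panel (haplotype causal-patterns convolved with
  themselves), so prevalence is exact even for correlated causal variants.
  Sampling is by rejection: each drawn individual becomes a case with its
  penetrance probability, else a control, until both quotas fill.
- **Polygenic inverse-logit** (`simulate_phenotype_prs`): per-individual
  score `sum_k logOR_k * g_k`, intercept calibrated by monotone
  root-finding (`brentq`, |sum expit - target| < 1e-8) so the expected case
  count hits the target, then independent Bernoulli draws. With all scores
  zero the intercept reduces to the logit of the target case fraction
  (e.g. `log(8021/16489) ≈ -0.721` for a 8021-of-24,510 case split).

Benchmark scenarios place causal variants deterministically: (1) the
common variant (MAF >= 0.2) nearest the central block's centre; (2) the
most strongly correlated eligible pair exactly three columns apart within a
block; (3) central common variants of two different blocks. All generators
are bit-reproducible given a seed; replicate r of a benchmark uses
`seed + r`.

## Evaluation metrics

Per replicate: simulate, associate, filter, LD + repair, fit, extract sets.
A causal variant is *detected* when it is a member of the union of that
replicate's credible sets (the union rule — detection in any set counts).
Power denominators include every replicate, including those with no sets;
"all" power requires every causal variant detected in the same replicate.
Set-size moments pool all sets across the replicates that produced at least
one set (per-replicate averaging is the documented alternative; pooling is
the default because the per-replicate set count is usually 0 or 1, where
the two coincide). Replicate-level failures are logged and counted, never
fatal.

## Problem sizes and determinism

The acceptance script runs the two headline scenarios at their stated
conditions — 100 replicates of 500 cases + 500 controls on the 300-variant
panel — in about 30 seconds on one CPU. The test suite uses smaller panels
(2-3 blocks of 10-30 variants) for pipeline tests and the full panel only
where the claim requires it. Every stochastic routine takes an explicit
integer seed and `numpy.random.default_rng`; identical seeds give
byte-identical outputs, including the full benchmark summaries.

## Known limitations

- No recombination-model haplotype simulation (block-AR thresholding only),
  no imputation, no X chromosome.
- The fitter consumes z-scores and a correlation matrix only
  (summary-statistic formulation); there is no individual-level-data
  variant and no refinement pass over the converged solution.
- Purity and credible sets assume the LD matrix used for fitting; supplying
  mismatched reference LD degrades both (by design, no correction is
  attempted).
- Covariate-adjusted association falls back to a per-variant Newton loop,
  which is accurate but not vectorised; with many covariates and many
  variants it is the slowest path in the package.
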