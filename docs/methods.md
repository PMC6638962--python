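# Methods

## Model and statistics

For samples `i = 1..n` with phenotype `y_i`, covariates `z_i` (q columns,
intercept included) and environment multipliers `x_i` (p columns, first
column 1), each locus `l` with dosage vector `g_l` is tested with the score
statistic of the added block `w_{l,i} = g_{l,i} x_i` in a generalized
linear model whose null part is `η_i = z_iᵀγ`:

    t_l = ũᵀ (Q W̃_l) (W̃_lᵀ Q W̃_l)^{-1} (Q W̃_l)ᵀ ũ,

with `W̃_l = Ω^{1/2} W_l`, `Ω = diag(ω_i)`, `Q = I − Z̃(Z̃ᵀZ̃)^{-1}Z̃ᵀ` the
projection complement of the weighted null design `Z̃ = Ω^{1/2} Z`, and
`ũ = Ω^{1/2} u = Ω^{-1/2}(y − μ̂)` the Pearson-scaled working residual.
Gaussian family: `ω ≡ 1`, `u = y`; logistic: `ω_i = μ̂_i(1−μ̂_i)`,
`u_i = (y_i−μ̂_i)/ω_i`.  On the Pearson scale the per-locus score vector
`W̃_lᵀ Q ũ` equals the classical score `W_lᵀ(y − μ̂)` at the null MLE and
its components have unit variance under a correct null, so `t_l` is
asymptotically χ²_p.  With `x_i = (1, E_i)` this is the 2df joint GxE test;
with `x_i = 1` it is the marginal 1df association test.  For Gaussian
models the unit-dispersion quadratic form is rescaled per locus,
`T_l = t_l / {(‖Q_Z y‖² − t_l)/n}`, which replaces the unknown residual
variance by its null estimate.

The genome-wide summary is `l_mean = mean_l(statistic)/p` (`T_l` for
Gaussian, raw `t_l` for binomial — the variance rescaling has no binomial
analogue, so the raw statistic is used there).

## The scan-free approximation

Assuming each `g_l` is i.i.d. across samples with finite moments and
independent of `(y, Z, X)`, the expectation of `t_l` over the genotype law
is, to terms of order 1/n,

    t_approx = tr(A^{-1}B),  A = Σ_i x̃_i x̃_iᵀ (Q)_{ii},  B = Σ_i x̃_i x̃_iᵀ (Qũ)_i²,

with `x̃_i = ω_i^{1/2} x_i`.  All genotype characteristics cancel, so the
quantity is computable before any scan.  `l_approx = T_approx/p` (Gaussian,
with `T_approx` defined by the same rescaling applied to `t_approx`) or
`t_approx/p` (binomial).  Two consequences follow directly and are used as
test oracles:

* Marginal Gaussian case (`x_i = 1`): `A = n−q`, `B = ‖Qy‖²`, hence
  `t_approx = rss/(n−q)` and `l_approx = n/(n−q−1)` *exactly*, independent
  of the data — the algebraic reason marginal scans look calibrated
  regardless of null-model quality, while the joint GxE test is sensitive
  to it.
* Under a correct null, `B ≈ E[ũũᵀ]`-weighted `A`, so `t_approx ≈ p` and
  `l_approx ≈ 1`.

The trace is computed by solving the p×p system `A s = B` (no explicit
inverse); p is small (≤ ~6 with multivariate environments) but skewed
environment variables can make `A` ill-conditioned, so a condition-number
guard (1e12) raises rather than returning noise.

A Monte-Carlo oracle (`mc_oracle_mean_t`) estimates `E_g(t_l)` by drawing
HWE genotypes `g ~ Binomial(2, maf)` and averaging actual statistics; tests
require agreement with `t_approx` within 3 Monte-Carlo SEs across families,
test modes and MAFs.  A screening convention flags `|l_approx − 1| > 0.1`
as "review" and `> 0.5` as "problematic"; both thresholds are arguments.

## Null-model fitting

Gaussian fits use `numpy.linalg.lstsq`; logistic fits use IRLS from
`γ = 0`, converging on max |score| < 1e-10 within 100 iterations, with
errors on non-convergence and on fitted probabilities within 1e-10 of 0/1
(quasi-separation).  Leverages and projections come from a thin QR
factorization of `Ω^{1/2}Z`; `(ZᵀZ)^{-1}` is never formed.  Rank-deficient
designs raise an error naming the collinear columns.  Missing values in
phenotype/covariates are handled by complete-case deletion (logged);
missing dosages are mean-imputed per locus so one null fit serves all loci.

## Simulation design

The scenario simulator generates, per replicate: covariate(s) and
environment from the scenario's distribution (standard normal by default;
five normals, uniform, Bernoulli(0.5) or ordinal {0..4} in the
distribution scenarios), genotypes as unlinked HWE loci with
MAF ~ Uniform(0.05, 0.5), and phenotype
`y = b_Z·Z + b_G·Σ g_c + b_GE·Σ g_c·E + ε` with ε ~ N(0,1) (or a Bernoulli
draw through the logit link), effects placed at 10 causal loci.  Scenario
modifiers: genotype frequencies shifted by 0.1 per SD of a latent factor
shared with Z and/or E (association scenarios); an omitted confounder with
unit effect (missed-covariate scenarios); a quadratic environment term
(coefficient 1, centered) fitted linearly (functional-form
misspecification); 1 or 10 samples displaced by 10 SD in phenotype and
5 SD in environment (outlier scenarios); latent-AR(1) LD with ρ = 0.8 and
a Beta(1,3) MAF spectrum rescaled to [0.05, 0.5] (genotype-law scenarios).
The LD generator thresholds two latent AR(1) Gaussian chains per sample at
the maf-matched quantile, so each locus stays marginally HWE.  The
association strengths, outlier magnitudes, quadratic coefficient,
causal-locus count, LD strength and Beta shape are package choices exposed
as `ScenarioSpec` fields; conclusions drawn from cells that depend on them
should be read as qualitative.

Replicate seeds are spawned from the master seed via
`numpy.random.SeedSequence`, making every replicate independently
reproducible.  Full scale is n ∈ {1000, 10000}, L = 10000, 200 replicates;
the default desk scale used by the test suite and the acceptance script is
n = 1000, L = 2000, 50 replicates, which keeps each scenario cell under
~15 s while leaving Monte-Carlo error well inside the tolerances used.

What the simulator does *not* emulate: population structure and cryptic
relatedness (the approximation's assumptions exclude them by design —
real-data use requires PC covariates), genotyping batch effects,
imputation dosage uncertainty, and realistic haplotype LD (the AR(1)
copula is a stand-in).  Passing tests therefore validate the approximation
under its stated assumptions, not robustness to structured cohorts.

## Box-Cox transformation

The transform `(y^λ − 1)/λ` (log at λ = 0) is applied to
`y − min(y) + 1`.  Two criteria: maximize the profile log-likelihood
(normality; via `scipy.stats.boxcox_llf`), or minimize `|l_approx − 1|` of
the transformed phenotype under the same null design.  Both use an
exhaustive grid λ ∈ [−5, 5] step 0.01 followed by bounded golden-section
refinement inside the winning cell; the grid contains λ = 1 (an affine
map), so the diagnostic criterion can never end worse than untransformed.
Grid search was chosen over derivative methods because `l_approx(λ)` can
be non-smooth and multi-modal; ties break toward the λ nearest 1
(least-distorting).  Degenerate transforms (numerically constant output)
are skipped.  Note the positivity shift changes which λ is optimal: a
lognormal phenotype whose shifted version is no longer lognormal will not
return λ = 0.

## Diagnostics and QC

Genomic-control λ is `median(t)/median(χ²_df)` or `mean(t)/df`; the df is a
required argument (the joint 2df test is adjusted against χ²₂).  Cook's
distances come from the standard hat-matrix formula (statsmodels) and are
flagged at `mean(D) + 4·sd(D)`; the multiplier is configurable, and on
clean data this rule flags roughly 1% of samples, so it is a screen, not a
test.  Variant QC excludes missingness > 0.05, HWE P < 1e-10 and
MAF < 0.05 (strict).  The HWE test is a Pearson 1-df chi-square against
expected genotype counts; exact-test implementations differ negligibly at
the 1e-10 threshold for common variants.

## Numerical conventions

Degenerate loci (monomorphic, or projected tested block with condition
number > 1e12) are skipped with NaN, not raised, and excluded from scan
means.  The vectorized scan is contractually identical (1e-10) to the
locus-by-locus path and is tested against it.  Gaussian rescaling requires
`rss_null > t`; violation (a saturated fit) raises.
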