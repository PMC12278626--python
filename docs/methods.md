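# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of the `sexde` package.

## The analysis problem

Two bulk RNA-seq cohorts of the human forebrain are compared: a prenatal
cohort spanning an active developmental window (first/early second
trimester) with repeated samples per individual, and an adult cohort.
The questions are (i) which genes are sex-differentially expressed
(sex-DE) in each cohort after adjusting for developmental progression,
and (ii) whether each gene's sex effect is specific to one life stage,
shared between them (and at what relative magnitude), or opposite.

Sex here means genetic sex inferred from sex-chromosome expression.
The logFC sign convention is log2(female/male): positive = female-biased.

## Sample sex assignment

Raw counts on two marker quantities — the sum over chrY protein-coding
genes and the *XIST* count — separate XY from XX samples by orders of
magnitude. A sample is labelled male iff chrY-sum exceeds its cutoff and
*XIST* is below its cutoff, female for the reverse; anything else is
unassigned and excluded. Cutoffs are data-set presets (7000/7000
symmetric for HDBR-style counts, 1000 chrY / 150 *XIST* for GTEx-style),
not tuned quantities. On synthetic cohorts with the default marker means
the assignment recovers the true sex of every sample.

## Normalization

Counts are filtered to genes with CPM > 1 in strictly more than 10
samples, then TMM normalization factors are computed following the
canonical published algorithm: reference = sample whose 75th
count-fraction percentile is closest to the mean, pairwise exclusion of
zero-count genes, 30% two-sided trimming on M-values and 5% on average
abundance, inverse-variance weighting, factors rescaled to geometric mean
1. The implementation is tested for equality against both an independent
naive re-implementation and edgeR's `calcNormFactors` on toy tables.
Expression values downstream are `log2((count + 0.5) / (lib * factor) * 1e6)`;
the prior count 0.5 is the conventional choice and only matters near zero
counts. Input to the trajectory and DE stages is log2-CPM rather than a
TPM-based unit because the synthetic data have no meaningful gene lengths;
the choice is recorded in run metadata (`config.yaml`).

## Pseudotime

The latent developmental coordinate is fit on the k most variable genes
(log-scale variance, deterministic lexicographic tie-break; k = 1000 in
the pipeline default) under

    y_gn = mu_g + c_g z_n + alpha_g x_n + beta_g x_n z_n + eps_gn

with x the female indicator. Inference is penalized alternating least
squares: per-gene ridge regressions (penalty 1e-6, for conditioning) given
z, then per-sample posterior means of z under a unit normal prior given
the loadings. Both half-steps minimize the same objective
`SSE + 1e-6*||theta||^2 + ||z||^2`, which is therefore non-increasing and
is asserted per sweep. Iteration stops when the relative objective change
falls below `tol` (default 1e-6) or at `max_iter` (default 500; a
non-converged fit returns the last iterate with a warning). z is
standardized on exit and its sign fixed by Kendall correlation with an
ordinal anchor when one is given, else by making the largest-|c| loading
positive.

Two design points deserve emphasis:

* **Initialization.** z starts at the first principal component of the
  *sex-centered* matrix (each sex group centered separately). The model is
  exactly invariant under `z -> z + g*x` with a compensating change of the
  per-gene sex effects, so a latent factor initialized on the raw first PC
  can converge onto the sex axis in data without a real trajectory — the
  factor would then absorb the very effects it is meant to adjust for.
  Sex-centered initialization keeps the fit in the covariate-orthogonal
  basin; the unit-normal prior then holds z there.
* **Identifiability of sex vs. stage.** Because of the same invariance, a
  sex difference in the *distribution* of developmental time is not
  separable from a sex effect on expression when time is latent. The
  estimator resolves the flat direction by making z orthogonal to sex. In
  data where developmental stage genuinely differs by sex, that choice
  reassigns the difference to the per-gene sex effects; this is a property
  of the model class, not of this implementation.

On synthetic prenatal cohorts (>= 30 individuals, trajectory effect sd
0.5 log2 units) the inferred z reaches Kendall tau >= 0.9 with the true
time at every tested seed; the acceptance threshold of 0.6 is passed with
a wide margin. Pseudotime-DE results are stable under permutation of the
sex covariate across individuals (~90-100% overlap of significant genes,
effect-size correlation > 0.9, with permuted refits sign-anchored to the
baseline coordinate).

## Differential expression

Each gene is fit by least squares on
`[1, sex, pseudotime, sex:pseudotime, extra covariates]` (categorical
extras are dummy-coded). Repeated samples per individual are handled by
cluster-robust covariance clustered on individual. Two flavours are
implemented: CR1 (Liang-Zeger with the G/(G-1)*(n-1)/(n-p) factor, t on
G - p df; with singleton clusters it reduces exactly to HC1, which is
tested against statsmodels) and the default CR2 (Bell-McCaffrey
bias-reduced linearization with per-coefficient Satterthwaite degrees of
freedom). CR2 is the default because CR1 is anti-conservative at moderate
cluster counts: at the default study conditions (60 individuals, 1-3
samples each) the measured type-I error at p < 0.05 is ~0.062 for CR1 and
~0.055 for CR2 (the residual excess over 0.05 traces to the negative
binomial data, not the estimator: the CR2 t reference is Monte-Carlo
exact under homoskedastic Gaussian noise on the same designs). The
linear-model-plus-cluster-robust combination deliberately replaces a full
variational mixed model with voom weights and surrogate variables: it
preserves the estimand (the group-level female-male contrast) while being
deterministic and dependency-free; shared technical factors that surrogate
variables would absorb are out of scope. Genes used to infer pseudotime
are excluded from the pseudotime-DE table (and its multiple-testing
correction) only.

Multiple testing uses Storey q-values: pi0(lambda) on the grid
0.05..0.95, smoothed with a cubic fit and read off at the largest lambda
(a fixed lambda is available), q = pi0-scaled Benjamini-Hochberg with
cumulative-min enforcement; significance at q < 0.01. The replication
rate pi1 = 1 - pi0(lambda = 0.5), clipped to [0, 1], estimated on the
replication p-values of discovery-significant genes; at a designed null
fraction of 0.54 it recovers 0.45-0.46 (the estimator has a small
downward bias because a few true effects land above p = 0.5).

## Line models

A gene's unknown effect pair beta = (beta_prenatal, beta_adult) is modelled
under K competing hypotheses, each a zero-mean bivariate Gaussian prior
concentrated along a line through the origin. A model with slope s and
scale tau has sd1 = tau, sd2 = |s|*tau and correlation sign(s)*cor; slope
0 and infinity degenerate onto the axes (dataset-specific effects). The
default model set is PRENATAL (0), SHARED0.5, SHARED1, SHARED2 (0.5/1/2),
ADULT (inf), OPPOSITE (-1), with tau = 0.1971916 — the 95th percentile of
|logFC| in a large prenatal sex-DE analysis divided by two, shipped as the
documented default so reruns of the original data are not required
(`compute_scale` implements the rule with linear interpolation, on
absolute values so the constant does not depend on the sign convention)
— and cor = 0.995 (0.990 for OPPOSITE). The observed pair b is beta plus
estimation noise with the per-gene SEs and an estimator correlation
r_lkhood (0 for independent cohorts; for cohorts sharing individuals it
is estimated as the Pearson correlation of logFCs over genes with
p > 0.10 in both).

The marginal likelihood of b under model k is the bivariate normal with
covariance prior_k + observation, evaluated in closed form (cross-checked
against numerical integration of the two-level hierarchy). Mixture
proportions pi follow a Dirichlet(1,...,1) prior and are estimated by
Gibbs sampling: sample per-gene assignments from the current membership
probabilities, then pi from the Dirichlet posterior; 2000 sweeps with 200
burn-in. Reported are the posterior mean and SD of pi and the
Rao-Blackwellized posterior-probability matrix (mean of per-sweep
membership probabilities — lower variance than assignment frequencies,
same mean). At six genes the sampler agrees with exhaustive enumeration
over all assignment vectors to within 0.01; on 2000 simulated pairs with
SEs <= 0.05 every mixture proportion is recovered within 0.022 of the
realized truth.

Genes are labelled shared when the three shared PPs sum above 0.8 (with
the single shared model exceeding 0.8 as sub-label, else "unspecified"),
prenatal-specific / adult-specific / opposite by their single PP > 0.8,
otherwise unclassified. The sub-label rule is this package's reading of
the shared breakdown; the threshold structure makes labels reproducible
from the PP matrix alone.

## Comparison and enrichment statistics

Cross-cohort comparison on the shared tested universe reports: direction
consistency (% of discovery-significant genes with the same t sign in the
other cohort, exact binomial test against 0.5), Pearson r of logFC over
the same genes, pi1 in both directions, direction-split overlap counts,
and an upper-tail hypergeometric test on the overlap. Gene-list
enrichment combines the upper-tail hypergeometric p (equal to exhaustive
enumeration on small universes) with an expression-matched permutation
test: universe genes are binned by expression decile (bin count is a
flag), each of B = 1000 permutations draws a random set with the query's
per-bin composition, and p = (1 + #{overlap >= observed}) / (B + 1). On
null queries drawn by the matching procedure itself the permutation p is
uniform (KS-tested). Enrichment is flagged significant when the
hypergeometric p beats alpha/(n_lists * n_gene_groups) — e.g.
0.05/72 = 6.9e-4 — and the permutation p beats 0.05. Two-proportion
contrasts (e.g. shared fraction among XCI escapees vs. inactive X genes)
use the chi-square test with Yates continuity correction, which
reproduces the printed reference values for both contingency tables
(p = 1.37e-8 and 9.52e-6).

## Synthetic study conditions

The generator produces two cohorts sharing one gene-level truth table.
Defaults (all overridable in `SimulationConfig`):

* 2500 genes; 60 individuals per cohort, 1-3 samples each, sex ratio 0.5
  — a desk-scale analogue of the real cohort structure.
* Sharing-category mixture (null, PRENATAL, SHARED0.5, SHARED1, SHARED2,
  ADULT, OPPOSITE) = (0.055, 0.60, 0.28, 0.02, 0, 0.005, 0.04), dominated
  by prenatal-specific and shared-with-attenuation effects.
* Non-null sex effects drawn N(0, 0.2^2) on the log2 scale (the scale of
  bulk-brain sex biases, mean |logFC| well below 1); the partner effect is
  then fixed exactly by the category geometry. X-linked escapees are
  forced to female-biased SHARED1 (escape from X inactivation is
  established early and stably maintained); inactive X genes follow the
  ordinary mixture.
* Developmental time t ~ Uniform(0, 1) per individual in the prenatal
  cohort, drawn *stratified within each sex* so the time distribution is
  sex-balanced — the condition verified in the real data (no male/female
  difference in pseudotime). This matters: with unconstrained draws a
  chance sex-time imbalance aliases into every gene's sex effect (see the
  identifiability note above), which is a genuinely different study
  condition, not extra noise. The adult cohort has no time signal.
  Per-gene time effects are N(0, 0.5^2) log2/unit-time; the
  sex-by-time interaction defaults to zero (only a small percentage of
  real genes show one) with a config field to enable it for power studies.
* Counts are negative binomial (dispersion 0.08) around log2-linear
  per-gene means converted to expected counts via per-sample relative
  proportions and library sizes Uniform(2e6, 6e6). Marker genes (one
  XIST-like, five chrY-like, mean count 3e4 in the expressing sex, exactly
  zero otherwise) are appended.
* Effect-pair SEs for the direct line-model input are log-uniform on
  [0.02, 0.2]; the real SE distribution of logFC estimates is not
  published, so this range is a stand-in spanning the relevant effect
  scale and is flagged in the config.

What the generator does **not** emulate: isoform/length structure (no
TPM), surrogate technical covariates and batch effects, individual-level
random expression offsets, cell-type composition, and region-specific
expression (region labels are cosmetic). Passing tests therefore
demonstrate correctness of the estimators under clean conditions, not
robustness to the technical structure of real RNA-seq.

All randomness flows from a single seed through fixed named substreams
(gene truth, effect pairs, per-stage sampling), so the two stage calls
share gene truth and byte-identical reruns are guaranteed at fixed
config.

## Problem sizes

Defaults are chosen so a full pipeline run (two cohorts, trajectory fits,
three DE analyses, 2000-sweep Gibbs) completes in a few seconds and the
entire test suite in well under a minute, while keeping >= 30 clusters for
the cluster-robust asymptotics and >= 2000 genes where mixture-recovery
precision is asserted. Recovery margins at these sizes: full-pipeline
mixture proportions within 0.03 of the realized truth across seeds
(asserted at 0.07 to leave room for ordinary seed-to-seed variation),
pseudotime Kendall tau >= 0.9 (asserted at 0.6).

## Known limitations

* The DE model is a fixed-effects approximation to a mixed model; with
  very few individuals or strong individual-level random effects the CR2
  correction loses calibration faster than a full mixed model would.
* Measured type-I error at the default conditions is ~0.055 rather than
  0.050; the excess is data-driven (negative binomial counts after
  log-CPM) and disappears under Gaussian noise.
* pi0/pi1 estimation uses a cubic-fit smoother rather than the original
  smoothing-spline; on typical p-value distributions the difference is in
  the third decimal.
* The line-model prior parameterization (sd2 = |slope|*scale, correlation
  sign(slope)*cor) is one concrete reading of "slope, scale, correlation";
  it satisfies the documented invariants (degenerate axis models,
  axis-swap symmetry with slope -> 1/s, SE -> 0 consistency) rather than
  matching any specific external codebase.
* Whether the original per-gene PPs were computed at the estimated
  mixture or averaged over the chain is not documented; this package
  reports the chain-averaged (Rao-Blackwellized) matrix.
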