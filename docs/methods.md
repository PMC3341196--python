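# Methods

This note records the models, the numerical choices, and the places where
the design was genuinely open.

## Data model and conventions

A `CountMatrix` is a genes × samples grid of non-negative counts with a
two-group sample assignment and per-sample library sizes (column sums by
default). All log-ratio statistics use base 2, with M oriented as group B
over group A: a gene higher in A has M < 0. Genes with a zero normalized
mean in either group have no defined M; they carry an explicit
undefined flag (NaN, never ±inf) and are excluded from every median and
trimmed statistic. Round-half-to-even is the single rounding rule used for
all count bookkeeping (number of DE genes, number of flagged genes,
RPM-rounding before the detector).

## TMM factors

For sample k against the reference r, using only genes positive in both
libraries,

    M_g = log2((y_gk/N_k) / (y_gr/N_r))
    A_g = 1/2 · log2((y_gk/N_k) · (y_gr/N_r))
    w_g = [ (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr) ]^(−1)

the factor is 2 to the w-weighted mean of M over the genes that survive a
double trim: the most extreme 30% of M per side and 5% of A per side
(rank-based, stable tie-break by gene index). The weights are the inverse
delta-method (binomial) variance of M. Defaults of 30%/5% correspond to
tolerating up to 60% DE with no directional bias; both are exposed as
options. The reference sample is the one whose upper quartile of
library-scaled counts is closest to the across-sample mean upper quartile
(lowest index on ties) — the choice only matters up to the final rescaling
of factors to geometric mean 1. Genes with a zero count in either member of
a pair are dropped from that pair rather than pseudo-counted.

## NB exact-test ranker

Libraries are first equalized: counts are rescaled to the geometric mean of
the effective library sizes, y′ = y·N̄/N_k, kept fractional until the test.
This deterministic, mean-preserving step replaces the stochastic
quantile-adjustment used by some qCML implementations; it preserves the
test's conditional structure while making results bit-reproducible.

The common dispersion maximizes the summed conditional NB log-likelihood of
within-group counts given group totals (terms constant in φ dropped),
optimized by golden-section search on log φ over [1e−6, 10] to 1e−4; a
boundary solution is reported as φ = 0 (Poisson-consistent). Tagwise
dispersions maximize each gene's conditional log-likelihood plus
`prior_weight` (default 10 equivalent observations) times the average
per-gene profile, interpolated from a 201-point log-φ grid — weighted-
likelihood shrinkage whose limits are the unshrunk per-gene maximizer
(weight 0) and the common value (weight ∞).

The exact test conditions on each gene's two-group total s of the rounded
equalized sums: Y_A ~ NB(n_A λ, size n_A/φ), Y_B ~ NB(n_B λ, size n_B/φ)
with λ = s/(n_A+n_B); the two-sided p-value sums all outcomes k = 0..s with
conditional probability ≤ the observed one (density method, not tail
doubling). φ = 0 uses the Poisson limit, where the conditional law is
binomial. Genes with s = 0 get p = 1 and an untestable flag. p-values
within 1e−9 of 1 are snapped to exactly 1 so that modal observations tie
robustly regardless of floating-point summation order.

## Empirical-Bayes detector

The detector consumes RPM-scaled data rounded to integers, with effective
sizes 10⁶·f_k (the TMM/TbT effective sizes rescaled to the RPM column
totals); RPM input empirically improves this detector's ranking. The
empirical prior is built by resampling `n_bootstrap` genes with replacement
(all-zero genes redrawn, cap 10·n_bootstrap): each draw is fitted once
pooled (one mean per unit effective library and one dispersion over all
samples — the no-DE component) and once with group-specific means and a
single shared residual dispersion (the DE component). Dispersion fits are
profile ML by vectorized golden-section on log φ; a flat-or-boundary
likelihood is reported as φ = 0. Sharing one residual dispersion across the
two group means (rather than fitting each group's dispersion on three
replicates) avoids degenerate φ = 0 particles and is the parameterization
under which the detector's P_DEG estimate is best calibrated.

Marginal likelihoods are averaged over particles in log space. The no-DE
likelihood averages the all-sample NB product over pooled particles. The DE
likelihood marginalizes the two groups **independently** over their
particle clouds; the average over particle pairs then factorizes into the
product of per-group averages. This independence is deliberate: it means a
null gene can only score well under the DE model if two separately drawn
particles both happen to match it, a built-in Occam penalty without which
the mixture-weight estimate below loses its anchor (for null genes
L_DE ≈ L_NDE, every posterior collapses to the current weight, and the
fixed point drifts to whatever the DE genes' mean posterior is).

The DEG proportion is the converged DE mixture weight: iterate
p ← mean_g [ p·L_DE / (p·L_DE + (1−p)·L_NDE) ] from p = 0.05 until
|Δp| < 1e−6 (cap 1000 iterations, non-convergence flagged). The top
round(p̂·G) genes by posterior (ties by index) are flagged; directions come
from effective-size-normalized group means, and P̂_A is the flagged
fraction higher in A (0.5 by convention when nothing is flagged). Under the
synthetic simulation conditions the estimator runs mildly conservative
(p̂ ≈ 0.13–0.16 at a true 0.20), consistent with its intended use: it is
better to eliminate slightly too few genes before renormalizing than to
trim aggressively.

## TbT pipeline

Step 1 TMM on raw counts; step 2 the detector above under step-1 effective
sizes; step 3 TMM on the raw counts restricted to non-flagged genes. The
final factors are step-3 factors × (column sums of the DEG-free submatrix)
/ (original library sizes), rescaled to geometric mean 1. "Library sizes
after eliminating the DEGs" is concretely the column sums of the retained
submatrix. If step 2 flags nothing the formula collapses and the step-1
factors are returned unchanged; if it flags everything the run aborts.

Iteration reruns step 2 under the previous round's TbT effective sizes and
recomputes step 3 (rounds labeled TbT, TbT1, TbT2, …; default 3 rounds).
Convergence is declared when the max per-sample |Δlog2 factor| < 1e−3 — a
declared tolerance, since no canonical criterion exists. The detector seed
is reused each round, so a converged factor vector is an exact fixed point.
An exact-test detector (flagging at p < α, default 0.05) is available as an
alternative step-2 engine.

## Simulator

Counts are NB draws (Poisson at φ = 0) with V = μ + φμ². Per-gene (μ, φ)
pairs are resampled **jointly** from a mean–dispersion table, preserving
the empirical coupling that dispersion is large where the mean is small.
The built-in synthetic table draws μ log-normal (log-mean 2.0, log-sd 1.5)
and sets φ = 0.1 + 2.5/μ with log-normal jitter (sd 0.3); these values give
a realistic overdispersed mixture of mostly low-count genes with a heavy
right tail of abundant ones, and users can substitute a table extracted
from real data via a two-column TSV. Exactly round(G·P_DEG) genes are DE
and round(·P_A) of those are up in A, positions placed by a seeded
shuffle. The fold change multiplies the up-regulated group's mean only
(one-sided inflation), putting 4-fold DEG clouds at M = ∓2 on an M-A plot;
the alternative model draws 1.2 + Gamma(shape 2.0, scale 0.5) per DEG
(minimum 1.2, mean 2.2). Defaults: 20,000 genes, 3 vs 3 replicates, 4-fold.

What the generator does not emulate: gene lengths and within-sample
effects, isoforms, correlated genes, lane/batch effects, and the exact
(μ, φ) distribution of any particular organism. Benchmark results here
demonstrate behavior under the NB model with biased DE — they bound, but
do not guarantee, behavior on real libraries.

## Evaluation

AUC is the Mann–Whitney pair-win probability of the ranked list against the
binary DE truth, computed from average ranks with half-credit ties (ties do
occur among posterior scores). Confusion metrics use the exact count
formulas. Median non-DE M is the median of defined-M true-non-DE genes
under a given factor set — the direct measure of residual normalization
bias. The Wilcoxon rank-sum comparison is two-sided, exact by enumeration
when the smaller sample has ≤ 10 values without ties, otherwise the
tie-corrected normal approximation (via scipy).

The benchmark harness runs, per (P_DEG, P_A) cell and trial: simulate →
normalize with each method → rank with each ranker → AUC, recording
per-trial AUC, P̂_DEG, P̂_A, flag confusion and median non-DE M. The
default desk-scale profile is 10 trials of 5,000 genes with 500 bootstrap
draws — sizes chosen so a full two-cell grid completes in about two
minutes on one CPU while leaving the comparisons (TbT vs TMM win counts,
rank-sum p-values) well resolved. The full-scale design (20,000 genes, 100
trials, 2,000–10,000 bootstrap draws) is available by flag.

## Known limitations

- The exact-test ranker is a deterministic analog of qCML machinery, not a
  numerical clone of any particular release of it.
- The detector's P_DEG surrogate (converged mixture weight) is one of
  several defensible definitions; it is conservative by a few percentage
  points under the synthetic conditions.
- The CLI's `rank` scores can differ from an in-process run at the last
  ULP for genes whose p-value ties at 1, since summation order depends on
  array alignment; rankings of testable genes are unaffected.
- Only two-group designs are supported; no GLMs, no multiple-testing
  calls (the pipeline consumes rankings, not significance calls).
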