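# Methods

`xtrait` implements a cross-trait comorbidity analysis of two GWAS from
summary statistics alone. This note records the models, the defaults and the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Data model and harmonization

A summary-statistics table carries, per SNP: identifier, position, effect and
other allele, log-odds effect `beta`, its standard error, p-value, sample
size, and optionally the effect-allele frequency. Validation drops rows with
missing identifiers (variants without rsIDs are excluded from all analyses),
non-positive standard errors or p-values, non-finite effects, or non-A/C/G/T
or identical alleles; drop counts are logged, never silent.

Harmonization aligns trait 2's effects to trait 1's effect allele. The allele
pair is matched directly, after allele swap (sign flip, EAF complement),
after strand complement, or after both; anything else is dropped and counted.
Palindromic (A/T, C/G) SNPs are strand-ambiguous and dropped by default; when
frequencies are present on both sides and both are at least 0.08 away from
0.5, an optional mode orients them by frequency agreement instead. The 0.08
margin makes a frequency-based call wrong only when the true frequency sits
implausibly close to 0.5 on one side.

LD is represented as a block-diagonal correlation structure: within-block
correlation matrices with unit diagonal, zero correlation across blocks. This
is the abstraction every stage shares (clumping, LD scores, locus grouping,
gene tests, simulation); a real reference panel reduces to it after block
partitioning, and SNPs absent from the reference are treated as singleton
blocks with a log line.

P-value-informed clumping visits SNPs in ascending trait-1 p-value (ties
broken by chromosome, position, ID, for determinism) and keeps a SNP iff its
r² with every retained SNP is below the threshold. The concordance analysis
clumps at r² < 0.1 — the same independence criterion the effective-gene-count
step uses — with the window equal to one LD block; MR clumps at r² < 0.001.
These thresholds are exposed, not hard-coded.

## SNP-effect concordance (SECA)

Independent SNPs are partitioned by twelve p-value cutoffs per trait (0.01,
0.05, 0.1, 0.2, ..., 0.9, 1.0), giving 144 nested subsets. Each cell gets a
two-sided Fisher exact test on the 2×2 table of effect directions
(concordant pairs on the diagonal); SNPs with a zero effect carry no
direction and are excluded with a count. Cells with no SNPs report a missing
test. The Fisher test is the conditional hypergeometric form (summing tables
with probability at most the observed), computed vectorized over all 144
cells via log-gamma arithmetic because the permutation null re-tests the
grid thousands of times; it is cross-checked against `scipy.stats.
fisher_exact` in the test suite.

Two grid summaries are computed. The excess-subset statistic counts cells
with OR > 1 and p ≤ 0.05; its nominal binomial reference uses a per-cell
null probability of 0.025 (significant **and** in the concordant direction).
The primary inference is the permutation test: each of `n_perm` (default
1000) iterations flips trait-2 signs independently per SNP — p-values, and
hence subset membership, are preserved — and the empirical p-value is
`(1 + #extreme) / (n_perm + 1)` with a Clopper–Pearson 95% CI. Both the
excess-subset count and the minimum cell p are permuted. Whether the
original concordance software permutes by sign flip or label shuffle is not
documented in the sources available to us; sign flipping is implemented
because it preserves each trait's marginal p-value structure exactly.

A calibration caveat: under the null the excess-subset count is usually 0,
so its permutation p has an atom at 1 and is conservative rather than
uniform — the unavoidable behavior of a permutation p for a discrete
statistic. The minimum-cell-p summary is effectively continuous and its
permutation p is uniform under the null; the test suite checks exactly
these two properties (validity for the count, KS uniformity for the min-p).

## LD-score regression

LD scores are `l_j = sum_k r_jk²` within the SNP's block, self-correlation
included. The univariate fit regresses `chi²_j` on `n_j l_j / m`; the slope
is the observed-scale SNP heritability and the intercept (1 in the absence
of confounding) may be freely estimated or constrained. Weights are the
single-step heteroscedasticity form `1 / (l_j (1 + n h² l_j / m)²)` with the
h² entering the weights taken from an unweighted pre-fit; this reproduces
the published estimator's two-step behavior to within jackknife error at
the scales exercised here, without its full iteration schedule. Chi-square
values above `max(80, 0.001 n)` are removed first (standard outlier
filtering). Standard errors come from a delete-a-block jackknife over 200
contiguous SNP blocks, reduced automatically (with a warning) for small m.

The bivariate fit regresses `z1 z2` on `sqrt(n1 n2) l / m`; the slope is the
genetic covariance and `rg = gencov / sqrt(h2_1 h2_2)` with the per-trait
fits run under the caller's intercept constraints. With no sample overlap
the genetic covariance intercept is constrained to zero (the default). The
rg standard error jackknifes the full ratio; its p-value is the two-sided
normal approximation. When either heritability estimate is non-positive the
correlation is reported missing with a diagnostic rather than as a complex
number or a wild ratio.

Case-control results are mapped to the liability scale by
`h²_liab = h²_obs · K²(1−K)² / (K_s(1−K_s) φ(z)²)`, z the standard-normal
quantile at 1−K. Note for K = K_s = 0.5 this factor is π/2. The published
endometriosis/migraine liability estimates themselves require the
consortium-held input data and are not desk-reproducible; the conversion
arithmetic is what the tests pin down.

One caveat: with constant LD scores and constant sample size the regressor
is constant and a free-intercept fit is unidentifiable; the code raises an
informative error instead of dividing by zero. LDSC needs LD-score
variation by construction.

## Cross-disorder meta-analysis

Per SNP, the fixed-effect combination is the inverse-variance-weighted mean;
Cochran's Q (df = k−1 = 1 for two studies) measures heterogeneity. The RE2
statistic is the likelihood-ratio test of `(mu, tau²) = (0, 0)` under
`b_i ~ N(mu, se_i² + tau²)`, with mu profiled in closed form and tau²
maximized on `[0, bound]` by bounded scalar optimization (the tau² = 0
boundary is checked explicitly; `xatol = 1e-12`). Its p-value uses the
asymptotic equal mixture `½χ²₁ + ½χ²₂`, slightly conservative for two
studies relative to tabulated small-sample corrections. Rows are flagged
`re2` when the heterogeneity p falls below 0.05, `fe` otherwise; classes are
genome-wide (p < 5e-8) and suggestive (p < 1e-5). Significant SNPs are
grouped into loci by LD-block membership with the smallest-p member as the
index SNP; block-based grouping is a documented choice, since locus
delimitation conventions vary.

## Two-sample Mendelian randomization

Instruments are exposure SNPs below 5e-8, harmonized against the outcome
(no proxy search; absentees are dropped with a log line) and clumped at
r² < 0.001. Each contributes a Wald ratio `by/bx` with first-order standard
error `sy/|bx|` (a second-order delta-method form is available behind a
flag). The approximate instrument-strength F-statistic is `(bx/sx)²`.

Estimators:

- **IVW** — inverse-variance-weighted mean of the ratios. The default is
  multiplicative random effects: the fixed-effect standard error is scaled
  by `max(1, sqrt(Q/(k−1)))`, so overdispersion widens the interval but
  underdispersion is never credited. On the worked 11-instrument table this
  reproduces the published standard error (0.05) where the fixed-effect
  form gives 0.03, which is why it is the default.
- **MR-Egger** — after orienting all exposure effects positive, a weighted
  regression of outcome on exposure effect with a free intercept (average
  directional pleiotropy). Standard errors apply the same no-underdispersion
  floor to the residual scale; p-values use t with k−2 df. Q′ is the
  weighted residual sum of squares about the Egger fit.
- **Weighted median** — ratios sorted, standardized cumulative weights
  `(cum_i − w_i/2)/Σw` interpolated at ½. The standard error is a seeded
  parametric bootstrap (default 5000 draws) that redraws exposure and
  outcome effects from their reported sampling distributions.
- **Modes** — Gaussian-kernel density mode of the (weighted) ratio
  distribution with bandwidth `phi · 0.9 min(sd, mad) k^(−1/5)` on a
  512-point grid (grid spacing bounds attainable precision); bootstrap
  standard errors; t reference with k−1 df.

Leave-one-out refits any estimator k times. The reverse-direction analysis
is the same pipeline with the datasets swapped; there is no separate code
path.

## Gene-based analysis and overlap

SNPs map to genes by interval containment (1-based inclusive, ±0 kb padding
by default; BED-dialect starts handled at the reader). The Best-SNP statistic
is the smallest SNP p in the gene, calibrated by Monte Carlo from
`z ~ N(0, R)` with the gene's LD submatrix (nearest-PSD repair with a log
line if needed), using the add-one empirical formula so p is never zero.
The simulation escalates tenfold until at least 10 exceedances are seen, up
to a cap (default 100× the initial size from the gene-table driver), keeping
relative precision roughly constant across small p-values.

Because neighbouring genes share or tag the same top SNP, counts of
significant genes are converted to effective counts: top SNPs are grouped
within LD blocks by chaining r² ≥ 0.1, and each group contributes the
Li–Ji eigenvalue count `Σ [1(λ≥1) + (λ − ⌊λ⌋)]` of its correlation
submatrix. The genome-wide gene threshold is `0.05 / Me_total`.

Cross-trait overlap at a gene-p threshold uses the one-sided exact binomial:
n = effective discovery-significant count, k = effective overlap (raw
overlap scaled by the discovery set's effective/raw ratio, rounded to an
integer), p0 = target effective-significant over target total effective.
The expected proportion is carried at three decimals — the precision at
which such proportions are reported — before the exact tail sum; pass
`p0_decimals=None` for full precision. Per-gene evidence across the two
traits is combined by Fisher's method (χ², 4 df), defined for p in (0, 1].

## Enrichment

Over-representation uses the hypergeometric upper tail within an explicit,
caller-supplied background; terms are restricted to 5–350 members (after
background intersection) by default. Adjustment is Benjamini–Hochberg; an
empirical family-wise mode (random same-size queries, family minimum-p
null) is available where an FWER-style adjustment is wanted. The proprietary
multiple-testing scheme of the original web service is not reimplemented,
so published adjusted p-values are not reproduction targets here.

## Synthetic data: what it shows and what it does not

The paired-trait generator draws per-SNP true effects from a bivariate
normal with variances `h2_k/m` and correlation `rg` (infinitesimal model;
a causal-fraction knob rescales the causal subset's variance), and observed
z-scores `z = sqrt(n) R b + e`, `e ~ N(0, R)` per block, independent across
traits (no sample overlap). Reported effects are on the z scale
(`se = 1/sqrt(n)`). Under this model `E[chi²] = 1 + n h² l/m` exactly, so
LD-score regression is correctly specified. Defaults are the conditions the
recovery tests exercise: m = 20 000 SNPs in AR(1) blocks of 50 with
rho = 0.5, n = 50 000 per trait, h² = 0.10 each, rg = 0.38.

The MR scenario generator draws exposure effects uniform on [0.09, 0.18]
with fixed standard errors, outcome effects `theta·bx + alpha` with
pleiotropy `alpha ~ N(mean, sd²)`, and ascertains instruments at genome-wide
significance by redrawing estimation noise for draws that would miss the
threshold — mirroring how real instruments are selected.

What passing recovery tests demonstrate: the estimators are consistent and
approximately calibrated under their own assumptions at realistic scales.
What they do not demonstrate: robustness to the features real GWAS data add
— liability-scale case-control sampling, sample overlap, population
stratification, allele-frequency-dependent architecture, imputation error,
long-range LD — none of which the generator emulates. Case-control traits
are exercised only through observed-scale statistics plus the liability
conversion arithmetic.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; pipeline reruns with the
same config are byte-identical. The recovery experiments use 20 seeds at
m = 20 000 for LDSC, 100 replicates for MR coverage, 50 runs × 99
permutations at m = 800 for the concordance null — sizes chosen to hold
Monte-Carlo error comfortably below each tolerance while keeping the whole
suite under a minute.

## Known limitations

- Two-study formulas are exercised throughout; Q and RE2 are k-general but
  the pipeline drives exactly two traits.
- RE2 p-values are asymptotic (no small-sample tabulation).
- No proxy-SNP lookup, MR-PRESSO, Steiger filtering or multivariable MR.
- The LD abstraction is block-diagonal; cross-block leakage in real panels
  is not modelled.
- The enrichment adjustment is BH (or empirical FWER), not the original
  web service's proprietary scheme.
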