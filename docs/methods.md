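# Methods

## Model

Phenotypes are standardised (mean 0, variance 1) and genotypes are additive
dosages with variance `q = 2p(1-p)`.  For the paired birth weight design the
generative model is

    Y1 = o * G_self + m * G_mother + e1        (own phenotype)
    Y2 = o * G_child + m * G_self  + e2        (offspring phenotype)

with direct effect `o`, maternal effect `m` and correlated residuals.  Under
additive Mendelian transmission without assortment, `Corr(parent, child)
genotype = 0.5` and `Corr(grandmother, grandchild) = 0.25`, giving the GWAS
expectations `E[b_own] = o + m/2` and `E[b_off] = m + o/2`, i.e.
`E[b] = A theta` with `A = [[1, .5], [.5, 1]]`.  The fertility model uses one
family-size outcome with female, male and sibling-specific effects and

    A = [[1, 0, .5], [0, 1, .5], [.5, .5, 1]]

(children mothered tag `f + s/2`, children fathered `m + s/2`, sibling count
`f/2 + m/2 + s`).  Both models are just-identified: `theta = A^{-1} b`.
The matrices encode assortment-free additive transmission; the sibling
matrix treats the sibling count as tagging each parental fertility effect at
0.5 plus a full sibling-specific effect, which is this package's model
definition for that design.

## Estimators

**Linear approximation.**  `theta = A^{-1} b` with covariance
`A^{-1} diag(se^2) A^{-T}`.  The diagonal covariance assumes disjoint GWAS
samples; under overlap the omitted negative cross term makes the reported
SEs conservative and the Wald tests deflate.  No overlap correction is
applied to the SE formulas — this is a documented limitation, demonstrated
qualitatively in the tests.

**Summary-statistics SEM.**  Per variant, observed covariance matrices are
rebuilt for three groups (own phenotype only over (G, Y1); offspring only
over (G, Y2); both over (G, Y1, Y2)) assuming allele frequency, beta and
phenotype variance are common to the groups.  The both-group Y1-Y2 entry is
`r_p * sqrt(V1 V2)` from a user-supplied phenotypic correlation `r_p`, and
the both-group size is the estimated sample overlap.  The implied
covariance uses the relatedness algebra above; in particular

    Cov(Y1, Y2) = q/2 (o^2 + m^2) + 1.25 o m q + c,

where the `0.25 o m q` part of the cross term comes from the
grandmother-grandchild path.  This expansion was verified against the
empirical covariance of the generative simulator (moment-match test) before
being trusted.  Fitting minimises the multi-group Wishart discrepancy
`F = sum_g (N_g - 1)[ln|Sigma_g| + tr(S_g Sigma_g^{-1}) - ln|S_g| - p_g]`
(the `N_g - 1` multiplier is the Wishart ML convention; immaterial at GWAS
sizes).  Because covariances built this way satisfy the model exactly, the
global optimum is analytic with `F = 0`; the fitter starts there and only
falls back to L-BFGS-B on `(o, m, log sigma1^2, log sigma2^2, c)` with up to
5 jittered restarts when the analytic candidate is infeasible (e.g. implied
negative residual variance at extreme betas — the reason low-MAF variants
are excluded at MAF < 0.5% for this estimator).  `c` is free only when the
both-phenotypes group is non-empty; with no overlap there are no data on the
phenotype covariance and `c` is fixed at 0.  SEs are observed information:
the inverse Hessian of `F/2`, computed by central differences with steps
`1e-3 * max(|theta_k|, 0.1)` (chosen so truncation and cancellation errors
are both ~1e-6 relative).  The table driver vectorises the analytic solution
and the Hessian across variants; it is cross-checked against the scalar
fitter in the tests.

**Overlap-aware solver.**  Stage one estimates the matrix of cross-trait LD
score regression intercepts `c_ij`, which equal the correlation
`N_s r_p / sqrt(n_i n_j)` between the estimation errors of the same
variant's betas in two GWAS sharing `N_s` samples.  Stage two applies the
closed form `theta = A^{-1} b`, `Cov = A^{-1} V A^{-T}` with
`V_ij = c_ij se_i se_j`.  For just-identified models this equals the
iterative DWLS solution, so no general SEM engine is implemented (scope is
restricted to just-identified models).  `c` off-diagonals are clamped to
±0.99 before building `V` (guaranteeing positive definiteness for K <= 3);
a non-PD user-supplied `V` is repaired by eigenvalue clipping with a
warning.  With `c = I` the solver reduces exactly to the linear
approximation — the tests assert this to 1e-10.

## LD score regression

Univariate: weighted regression of `z^2` on `n * l / M`; bivariate:
`z1 z2` on `sqrt(n1 n2) l / M`.  Weighting is two-step: a first pass with
heteroskedasticity weights `1 / max(l, 1)`, then a second pass with weights
proportional to the inverse conditional variance implied by the first-pass
fit (`2 (a + b x)^2` univariate, `e1 e2 + e12^2` bivariate, floored at
0.05).  SEs come from a delete-one block jackknife over position-contiguous
blocks: 200 blocks by default, `floor(n_snps / 50)` for small panels, with
at least 200 variants required.  Genetic correlation is
`rg = gcov / sqrt(h2_1 h2_2)` from the three slopes, with the jackknife
applied to the ratio over shared blocks; non-positive heritability estimates
flag `rg` as undefined rather than reporting a complex number, and `|rg| > 1`
is reported with an out-of-range flag rather than truncated.  Overlap
conversion is `N_s = intercept * sqrt(n1 n2) / r_p`, clamped to
`[0, min(n1, n2)]` with the raw value retained; the modified intercept
formula that corrects for population stratification is deliberately not
used.  Estimates are reported raw — cryptic relatedness between GWAS can
inflate the intercept and hence the overlap estimate, and no correction for
this is attempted.

## Simulator

`simulate_families` draws founder genotypes (mother, father, mate) under
Hardy-Weinberg at per-variant frequencies (default Uniform(0.05, 0.95)),
transmits alleles by fair Mendelian draws to the focal individual and their
child, and builds phenotypes from per-variant conditional effects plus
correlated Gaussian residuals.  Variants are simulated in linkage
equilibrium: the per-variant estimators never use LD, so LD enters only
through `simulate_ldsc_zscores`, which draws z-score pairs directly from the
bivariate LD score regression expectation over a synthetic LD-score panel
(scores `1 + Gamma(2, mean/2)`).  Fertility outcomes are Gaussian latent
family-size scores, matching the linear-GWAS treatment of count phenotypes.

Defaults define the emulated study: residual scales are completed so each
phenotype has unit total variance (the GWAS this mirrors z-scored its
phenotypes), and the residual correlation is solved so the total phenotypic
correlation between own and offspring outcome equals 0.24, the value used
throughout the overlap arithmetic.  Overlap designs place
`round(fraction * n_families)` families in both GWAS and split the rest
evenly.  One master seed expands into independent child streams (founders,
transmission, noise, masks) so components are individually reproducible;
all outputs are bit-reproducible under a fixed seed.

What the simulator does *not* emulate: LD between causal variants,
imputation noise (INFO), assortative mating, multi-generation dynastic
structure beyond trios, relatedness within or across GWAS samples, and
count-valued fertility phenotypes.  Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to these real-data complications (the intercept-based overlap estimate in
particular is known to absorb cryptic relatedness in real data).

## Calibration metrics and test scales

Standard-error calibration is assessed as the standard deviation of
per-variant standardised errors `(theta_hat - theta_true) / SE`, which is 1
for a calibrated estimator.  (The ratio of the raw SD of estimates to the
mean reported SE is biased upward by several percent when allele frequencies
— and hence per-variant SEs — vary, a Jensen-inequality artefact, so the
standardised form is used.)  Simulation scales were chosen to keep the whole
suite at desk scale while leaving Monte-Carlo error well below the tested
tolerances: 20,000 families with 200 variants for parameter recovery, 500
variants for the overlap calibration contrast, and 120,000 sampled null
variants (drawn from the exact sampling distribution of the unadjusted
betas, the same oracle used for the solver's Monte-Carlo covariance check)
for type-I error at alpha = 0.05 and 1e-3.

Under correctly specified overlap, the SEM's observed-information SEs are
~2% anti-conservative relative to the true sampling spread of the
marginal-GWAS-derived estimates: the joint three-group likelihood implies
slightly more information than two marginal GWAS actually carry (a
seemingly-unrelated-regressions efficiency gap).  This is a property of
feeding marginal summary statistics into a joint model, is the same
mechanism that deflates SEM SEs when overlap is spuriously estimated on
disjoint GWAS, and is why the null-calibration test exercises the SEM in
its exactly-specified no-overlap configuration.

## Harmonization rules

Tables are aligned on shared variant IDs and re-oriented to a canonical
effect allele (alphabetically first), flipping beta and frequency as needed,
so the result is independent of input orientation.  Variants are dropped
with logged reasons when absent from a table, strand-ambiguous (A/T, C/G;
optional), carrying irreconcilable alleles (exact strand complements are
reconciled only when ambiguous variants are being kept, i.e. when the data
are assumed strand-consistent enough to interpret complements), differing
in effect-allele frequency by more than 0.2 after orientation, or rarer
than `maf_min` in any table.  Chrom/pos disagreements for a shared ID are
warned about but not fatal — positions are used only for locus windows.
Coordinates are 1-based; no liftover is attempted.

## Post-processing conventions

Loci are greedy 500 kb windows: repeatedly take the most significant
remaining variant below 5e-8 not within 500 kb of a chosen sentinel on the
same chromosome, with ties broken by (chrom, pos, variant_id).  Novelty
against a known-sentinel list is strict: exactly 500 kb away is known,
500,001 bp is novel.  The heterogeneity statistic
`Q = (b1 - b2)^2 / (se1^2 + se2^2)` is chi-square(1) under the null for
independent estimates; applied to two methods run on the same data it
ignores their (positive) correlation and is then conservative for detecting
method disagreement in opposite-signed errors and liberal for shared-sample
noise — flagged wherever it is exposed.
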