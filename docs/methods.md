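# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the design decisions behind `mrtier`, in the order the
pipeline runs them.

## Summary-statistic model and harmonisation

All stages operate on per-variant summary associations (effect allele, other
allele, frequency, per-allele beta, SE, p, N). Betas for case-control traits
are log-odds. Validation drops rows with non-positive SEs, p-values outside
(0,1], identical alleles, frequencies outside (0,1), or a p-value
inconsistent with |beta/SE| under the two-sided normal approximation beyond
10% relative tolerance; drops are logged with reasons.

Harmonisation matches variants by identifier only (synthetic data controls
identifiers, keeping matching deterministic), flips swapped-allele outcome
records (beta → −beta, f → 1−f), and retains palindromic (A/T, C/G) variants
only when both frequencies fall on the same side of 0.5 and outside the
ambiguity band [0.42, 0.58]. The band limit is configurable; 0.42 follows
standard two-sample-MR harmonisation practice. Harmonisation is idempotent,
and flipping both alleles plus the beta sign in an input file leaves the
harmonised output bit-identical.

Positions are 1-based; all genomic windows are closed on both ends. All
synthetic data uses one fictional genome build, so no coordinate lift-over
exists anywhere in the package.

## Instruments

Clumping is greedy: candidates with p ≤ 5×10⁻⁸ are visited in ascending p
(ties broken by chromosome and position for determinism); each retained index
variant removes remaining candidates within 10,000 kb with panel r² ≥ 0.001.
Variants on different chromosomes are treated as exactly independent.
Candidates absent from the LD panel are dropped (conservative) rather than
assumed independent. Instrument strength is the single-variant approximation
F = (beta/SE)²; variants with F < 10 are excluded after clumping. A variant
is cis when within ±1 Mb of the annotated gene body, trans otherwise; in
cis_only mode trans variants are removed before clumping, in cis_and_trans
mode all candidates are clumped jointly.

## MR estimators

* **Wald ratio** (1 instrument): beta = βᵧ/βₓ with the two-term delta-method
  SE sqrt(sᵧ²/βₓ² + βᵧ²sₓ²/βₓ⁴); two-sided normal p-value.
* **IVW** (≥ 2): zero-intercept weighted regression of βᵧ on βₓ with weights
  1/sᵧ², i.e. beta = Σwβₓβᵧ / Σwβₓ². The fixed-effect SE 1/sqrt(Σwβₓ²) is
  inflated by max(1, sqrt(Q/(k−1))) — multiplicative random effects, so
  heterogeneity widens but never narrows the interval. Cochran's
  Q = Σw(βᵧ − beta·βₓ)² is referred to χ²(k−1).
* **MR-Egger** (≥ 3): weighted regression with intercept after re-orienting
  pairs to non-negative exposure effects; slope and intercept use t
  inference with k−2 degrees of freedom and the regression-estimated
  residual scale, which is what keeps the intercept test calibrated when
  balanced pleiotropy adds between-instrument variance.

Wald/IVW p-values use the normal distribution. Whether the analysis-level
IVW is fixed- or random-effects is exposed as the SE-inflation rule above;
the multiplicative-random-effects default matches common two-sample-MR
software behaviour.

Multiple testing: BH step-up q-values over the pooled results of a run (a
per-outcome option exists but is off by default), and a Bonferroni gate at
the exact ratio alpha/n_tests. Display rounding (2×10⁻⁶ for 0.05/24,598;
9.7×10⁻⁶ for 0.05/5,152) is presentation-only; gates always use the exact
ratio.

## Steiger directionality

Variance explained per variant: 2f(1−f)β² for quantitative traits with a
unit-variance phenotype, or z²/(z²+n−2) from the p-value and sample size.
Case-control traits always use the p/n form with the effective sample size
n·cf·(1−cf) — the same effective-n that scales their SEs — keeping
quantitative and binary traits on a comparable observed scale; without this,
mixed-type comparisons are systematically biased toward the quantitative
trait and reverse causation with a binary outcome is undetectable. Per-
instrument r² values are summed (capped at 1 with a warning). The direction
is correct when the exposure sum exceeds the outcome sum; a Fisher-z
comparison of the two correlations, using the smaller of the two effective
sample sizes, gives the Steiger p-value. The tier gate uses direction only
by default; an optional p-value threshold can be enabled.

## Colocalisation

Per-SNP evidence is the Wakefield approximate Bayes factor with sampling
variance v = SE² and prior effect variance w; the prior effect s.d. is 0.15
for quantitative traits and 0.2 for case-control traits (log-odds), the
published defaults of the underlying method. Hypothesis sums over all
single-causal-variant configurations use per-SNP priors p1 = p2 = 1×10⁻⁴ and
p12 = 1×10⁻⁵ (config-overridable); H3 is computed in log space as
log(Σᵢe^{l1ᵢ}·Σⱼe^{l2ⱼ} − Σᵢe^{l1ᵢ+l2ᵢ}) via a guarded log-diff-exp, and the
five posteriors are normalised by log-sum-exp. Posteriors match a
brute-force enumeration of configurations to ~1×10⁻¹⁴ and always sum to 1
within 1×10⁻⁹.

### Conditional analysis

Joint/conditional effects are estimated from marginal statistics and the LD
panel (COJO-style normal equations). X'X is approximated by the panel's
empirical dosage covariance scaled by the GWAS sample size (per-variant
effective n for case-control traits), and X'y is recovered from the marginal
estimates. Using the panel's empirical covariance rather than the
Hardy-Weinberg 2f(1−f) approximation has a useful property: when the panel
*is* the GWAS sample, conditional estimates equal individual-level multiple
regression exactly, and with an external panel the approximation quality is
the same as the frequency-based form. Conditional SEs rescale the observed
marginal SE by the conditioning variance-inflation factor
sqrt(D/(D − aᵀA⁻¹a)); this deliberately does not re-estimate the residual
variance from a joint-model RSS, so conditioning on an uncorrelated variant
leaves a variant's statistics exactly unchanged (and the SE is mildly
conservative when the conditioning set explains much phenotypic variance).
Variants whose multiple-r² with the conditioning set exceeds 0.9 are omitted
as collinear; variants whose GWAS frequency differs from the panel's by more
than 0.2 are dropped.

Stepwise signal selection is forward-only: add the variant with the smallest
(conditional) p while it passes 5×10⁻⁸, recompute, repeat (cap 10 signals).
Pairwise conditional colocalisation then tests the marginal–marginal pair
plus every conditional-exposure × conditional-outcome pair (a side with at
most one signal contributes its marginal statistics), reporting all pairs
and the maximum H4.

## Tiering

Seven boolean gates feed a pure classifier: Bonferroni (p ≤ 1.8×10⁻⁶ by
default — the tier definition's stated threshold; the 0.05/24,598 ≈ 2×10⁻⁶
variant is available by config, and the package logs which is in use), FDR
(q ≤ 0.05), Steiger direction, colocalisation (max H4 ≥ 0.8), cis-only
instruments, heterogeneity (Q p > 0.05, gated only when more than 2
instruments) and pleiotropy (Egger intercept p > 0.05, gated only when more
than 3). Tier A requires all gates except FDR; Tier B swaps Bonferroni for
FDR; Tier C is Tier B with trans instruments allowed; FDR-significant
findings failing another gate are "fdr_only"; the rest "none". The 2⁷ truth
table is asserted exhaustively in the tests. The region tested for
colocalisation is chosen per the cis-precedence rule: any cis instrument
(smallest p among cis) beats any trans instrument; with only trans
instruments the smallest-p trans variant is used; a singleton instrument is
used regardless of locality. Cross-QTL colocalisation between the tiered
QTL datasets of one biomarker is skipped when either dataset's signal lies
in the MHC.

## Synthetic data

The LD panel draws two independent haplotypes per individual from a latent
first-order autoregressive Gaussian (adjacent-variant correlation rho = 0.9
within blocks of 25 variants, independence across blocks) thresholded at
target allele frequencies drawn uniformly from (0.05, 0.5); dosages are
haplotype sums, so Hardy–Weinberg holds by construction and realised LD is
the tetrachoric-attenuated image of the latent AR(1).

GWAS are generated on the summary level: with panel correlation R and
standardised causal effects β_std, true standardised marginals are R·β_std;
observed effects are drawn independently around the truth with SE
1/sqrt(n_eff) (n_eff = n for quantitative traits, n·cf·(1−cf) for
case-control). Per-allele effects divide by sqrt(2f(1−f)). An
individual-level slow path (explicit genotypes, phenotype regression) exists
solely as the oracle for conditional-analysis and variance-explained checks.
The fast path does not model correlated sampling noise across variants,
sample overlap, imputation error, or realistic human LD maps — so passing
tests demonstrate correctness of the estimators under the stated sampling
model, not robustness to those real-data features.

The scenario suite uses one 0.8-Mb region of 200 variants, an LD panel of
7,733 individuals (a realistic reference-cohort size), exposure n = 30,000
(quantitative QTL) and outcome n = 50,000 with case fraction 0.2. Scenario
effect sizes (standardised): a cis QTL of 0.225 per allele-s.d. (|z| ≈ 39,
F ≈ 1,500); causal effects on the outcome of 0.4 (Tier A; outcome |z| ≈ 8)
and 0.27 (Tier B; |z| ≈ 5.5 — strong enough for colocalisation evidence yet
frequently below the Bonferroni line, so the recorded expectation for that
scenario is "cis, colocalising, FDR-significant", i.e. tier A or B, since no
effect size can pin an exact-B call reproducibly against unit sampling
noise). The trans scenario places the gene on another chromosome; the
distinct-variant scenario puts the outcome's causal variant in a different
LD block (r² < 0.3); reverse causation makes the exposure signal a halved
echo of the outcome's; heterogeneity adds per-instrument jitter
(s.d. 0.04) to six instruments' outcome effects; directional pleiotropy adds
a constant 0.18 per-allele direct effect to all six instruments.

## Validation studies and sizes

All reported quantities are recomputed at run time by
`scripts/acceptance.py` (and asserted by the acceptance test module):
threshold arithmetic (exact); coloc enumeration equivalence over 50 regions
of ≤ 20 SNPs; IVW bias and coverage over 500 replicates of 10 valid
instruments (true effect 0.2, n = 20,000/50,000); Egger calibration over
2,000 replicates of 10 instruments with balanced (s.d. 0.01) or directional
(mean 0.01) pleiotropy at exposure n = 100,000 — chosen so measurement error
in the exposure effects is negligible and the intercept estimand is the
pleiotropy mean itself; colocalisation discrimination and the conditional-
colocalisation rescue scenario over 100 seeds each; conditional-analysis
accuracy against individual-level regression at n = 10,000 with 2–5 causal
variants; Steiger direction recovery over 200 seeds; and the full scenario
suite end to end over 20 seeds per scenario.

## Known limitations

* Single-region, single-gene synthetic geometry; no genome-scale multi-gene
  cis assignment or proxy-variant lookup.
* Case-control modelling is entirely on the observed (effective-n log-odds)
  scale; no liability-scale conversions.
* The conditional-SE rescaling is conservative under heavy conditioning.
* Weighted-median/mode estimators, MR-PRESSO, multivariable MR and
  SuSiE-style colocalisation are out of scope.
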