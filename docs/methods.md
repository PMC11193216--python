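# Methods

## Model and assumptions

Two-sample MR treats each SNP j as an instrument: γⱼ is its effect on the
exposure (with SE σ_γⱼ) from one GWAS, Γⱼ its effect on the outcome (SE
σ_Γⱼ) from another. Under the instrumental-variable assumptions (relevance,
independence from confounders, exclusion restriction), each Wald ratio
βⱼ = Γⱼ/γⱼ estimates the causal effect; its first-order SE is σ_Γⱼ/|γⱼ|,
which ignores the sampling error in γⱼ — adequate when instruments are
strong (the F > 10 filter keeps the neglected term below ~10% and in
practice, with the genome-wide-significance floor, far below that).

All binary-trait effects are on the log-odds scale; odds ratios and their
95% intervals are exp(β ± 1.96·SE).

### Univariable estimators

* **IVW**: β̂ = Σwⱼβⱼ/Σwⱼ with wⱼ = 1/SE(βⱼ)², fixed-effects SE (Σwⱼ)^(−1/2).
  Heterogeneity is judged by Cochran's Q = Σwⱼ(βⱼ−β̂)² against χ²(nSNP−1);
  when its p < 0.05 the SE is multiplied by √(Q/(nSNP−1)) (multiplicative
  random effects). The factor is floored at 1, so a random-effects model
  never claims more precision than the fixed-effects one.
* **MR-Egger**: weighted regression of Γⱼ on γⱼ with a free intercept,
  weights 1/σ_Γⱼ², after flipping each (γⱼ, Γⱼ) pair so γⱼ > 0. The
  intercept estimates average directional pleiotropy; slope and intercept
  SEs carry the same over-dispersion factor max(1, √(RSS/(n−2))).
* **Weighted median**: order the ratios, interpolate at standardized
  cumulative weight 0.5 (sⱼ = (cumⱼ − wⱼ/2)/Σw). Consistent when valid
  instruments hold ≥50% of the weight. SE from a parametric bootstrap
  (βⱼ* ~ N(βⱼ, SEⱼ), 1000 replicates, fixed seed, weights held fixed).
* **Weighted mode**: argmax of a weighted Gaussian kernel density over the
  ratios, bandwidth 0.9·min(sd, IQR/1.349)·n^(−1/5) times a configurable
  factor (the modified Silverman rule); the argmax is located on a 512-point
  grid and refined by bounded golden-section search. Consistent when the
  largest cluster of instruments is valid. Bootstrap SE as for the median.

P-values are two-sided normal throughout, matching the large-sample
convention for two-sample MR (a t option is deliberately omitted: at the
instrument counts this pipeline targets the difference is negligible).

### Sensitivity battery

Leave-one-out re-runs IVW without each SNP (re-deciding fixed vs random per
subset). MR-PRESSO is re-implemented: the observed standardized residual sum
of squares about each SNP's leave-one-out IVW prediction is compared with
parametric simulations (Γⱼ* ~ N(β̂₍₋ⱼ₎γⱼ, σ_Γⱼ²), γⱼ* ~ N(γⱼ, σ_γⱼ²));
per-SNP outlier p-values are Bonferroni-adjusted by nSNP; when outliers are
flagged, the distortion test compares the IVW shift after their removal
against removal of equally many random SNPs, and the corrected estimate is
the ordinary IVW on the outlier-free subset. All Monte-Carlo p-values use
the (r+1)/(n+1) correction, so they are never exactly zero. The default
1000 simulations keeps a desk-scale runtime; note that with the Bonferroni
adjustment the smallest attainable adjusted p is nSNP/(n_sim+1), so flagging
outliers among ~50 instruments requires n_sim ≥ 1000.

### Mediation

Proportion mediated = (β₁·β₂)/β₀, indirect-effect SE by the product delta
method √(β₁²σ₂² + β₂²σ₁²). The default CI divides the indirect effect's CI
by β₀ (treating the total effect as fixed); a full three-term delta method
and a parametric bootstrap are available via `ci_method`. Eligibility for
the second step requires both links causal (IVW p < α) and neither Egger
intercept p < 0.05. Proportions outside [0, 1] (inconsistent mediation) are
reported verbatim with a warning, never truncated.

### Multivariable MR

MV-IVW is no-intercept WLS of Γ on the nSNP×k exposure-effect matrix,
weights 1/σ_Γ², SEs floored by max(1, √(Q_mv/(n−k))); a companion fit with
an intercept supplies the pleiotropy diagnostic. MV-median minimizes
Σwⱼ|Γⱼ−θ'γⱼ| by iteratively reweighted least squares (tolerance 1e−8,
denominator floor 1e−10), SEs by parametric bootstrap of both Γ and the
exposure effects. MV-LASSO augments the model with per-SNP intercepts αⱼ,
penalized by λΣ|αⱼ| while θ stays unpenalized, solved by alternating
soft-thresholding and WLS; λ runs log-spaced over 50 points from λ_max (the
smallest penalty zeroing every αⱼ) down to 10⁻⁴λ_max, scanned from the
largest value down, stopping at the first λ whose retained (αⱼ = 0) SNPs
are homogeneous (Q ≤ its degrees of freedom); θ is then re-estimated by
MV-IVW on the retained set. Because Q fluctuates around its df even for
clean data, the stopping rule can occasionally drop a few valid SNPs beyond
the truly pleiotropic ones; the tests therefore assert that planted
outliers are a subset of the exclusions rather than the exact set.

MVMR instruments are the union of each trait's significant clumped SNPs,
re-clumped jointly by lowest p across traits and harmonized to the outcome;
SNPs missing from any trait are dropped with provenance. A causal relation
is considered to survive adjustment when at least one of the three methods
is significant.

## Harmonization and instrument selection

Harmonization aligns every trait's effect to the exposure's effect allele:
swapped alleles negate β and reflect the allele frequency; complement-base
configurations are reconciled as strand flips before dropping anything.
Palindromic (A/T, C/G) SNPs are oriented by allele frequency and dropped as
ambiguous when any trait's MAF is within 0.08 of 0.5 (configurable) or when
a frequency is missing. Harmonization is idempotent, and duplicated SNP ids
keep the lowest-p row.

Clumping is greedy in ascending p (ties broken by chromosome, position, id,
so results are independent of input row order): a candidate within the
window of a kept SNP is removed when their r² ≥ 0.001, taken from a
user-supplied pairwise r² table; absent such a table, distance alone removes
(SNPs on different chromosomes or ≥ window apart are treated as
independent). The package never computes LD from genotypes. The F > 10
filter is applied to the selected instruments before harmonization; reverse
MR reuses identical thresholds.

## Synthetic-data generator

The generator emulates the statistical skeleton of GWAS summary tables, not
their genomic texture. Per SNP: allele frequency ~ U(0.05, 0.95); SEs from
the standard approximation 1/√(2·MAF·(1−MAF)·N) (binary traits on the
log-odds scale via an effective-N argument); true exposure effects folded
normal, sd 0.02 by default, floored at (z₅ₑ₋₈ + 5)·SE so every intended
instrument passes selection even after sampling noise; observed effects add
N(0, SE²) noise and p-values are exactly consistent with (β, SE). Effect
alleles are oriented to the exposure-increasing allele — the common
reporting convention — which also makes directional pleiotropy (αⱼ added to
Γⱼ with nonzero mean) directional on the ratio scale; without that
convention, symmetric γ signs would cancel the bias directional pleiotropy
is supposed to induce. Default sample sizes mirror the study conditions:
exposure N = 659,316, mediator N = 400,792, outcome N = 28,655.

Mediation datasets add a mediator with δⱼ = b₁γⱼ plus an equal-sized block
of mediator-specific instruments; the outcome is direct·γⱼ + b₂δⱼ, so the
implied total effect is direct + b₁b₂ and the true proportion mediated is
b₁b₂/(direct + b₁b₂). Multivariable datasets draw SNP effects on k
exposures from a multivariate normal with configurable correlation,
rescaling rows that would miss significance for every exposure. The
four-trait study generator chains these together (with covariate loading on
the exposure's instruments and outcome-specific instruments so reverse MR
is estimable).

What the generator does **not** model: LD between instruments (clumping
fixtures plant correlated pairs explicitly), winner's curse, sample overlap
between the two GWAS, allele-frequency–dependent architecture, and
population stratification. Passing tests therefore demonstrate correctness
of the estimators under the stated sampling model, not robustness to those
real-data complications.

## Validation scenarios and problem sizes

The test suite's statistical checks run at sizes chosen to keep the whole
suite under a minute while leaving Monte-Carlo noise well inside the
asserted bands: estimator calibration uses 500 replicates of 50 instruments
(IVW coverage, Egger intercept type-I error); robustness uses 200
replicates of 100 instruments with 40% directionally invalid ones — for
that scenario the instrument-effect sd is 0.25 and the pleiotropy offsets
N(0.08, 0.02²), fixed by a-priori power analysis so the weighted median's
predicted bias (~0.017) sits well under the 10%-of-effect bound while IVW's
(~0.10) clearly exceeds 25%; mediation recovery uses 500 replicates of
100–200 instruments with effect sd 0.05, because at the 0.02 default and
the CAC-scale outcome N the total-effect estimate is noisy enough that the
ratio's convexity bias alone would exceed the recovery tolerance — the
recovery checks target the effectively-unbiased regime. MR-PRESSO
calibration checks the global p's uniformity over 200 null replicates.

## Numerical choices and degenerate inputs

1.96 is used for all 95% intervals (matching reported tables). Identical
ratios give the weighted mode/median a zero bootstrap SE and a degenerate
p (0 or 1 by sign). Zero exposure effects are excluded from Wald ratios
with a log entry; a single surviving instrument must use the explicit
single-SNP Wald path. β₀ = 0 makes the proportion mediated undefined and
raises. Estimator minimums (IVW 2, Egger/median/mode 3, MR-PRESSO 4,
MVMR k+1) raise typed errors. All stochastic steps take explicit seeds;
the pipeline derives per-analysis seeds deterministically from the config
seed, making every output table byte-reproducible.

## Known limitations

No proxy-SNP lookup for variants missing from the outcome GWAS, no Steiger
filtering, no RAPS/contamination-mixture estimators, no MVMR-Egger slope
(only the intercept diagnostic), no conditional F-statistics, single-pass
MR-PRESSO (no iterative re-testing), no genome-build liftover, and no
multi-allelic variants. The difference-method mediation decomposition
(β₀ − direct effect) is intentionally not implemented; the product method
above is the package's definition.
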