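# Methods

This note records the statistical model, the synthetic-cohort design, the
numerical conventions and the open design choices behind `gxescore`.

## Models and selection

Each SNP is tested with three identity-link Gaussian models fitted by
ordinary least squares (equivalent to the standard GLM default for a
continuous response, as in R's `glm`):

* **Diet model** (9 terms): Δbodyfat on intercept, gender, age, ΔTC, SNP,
  ΔC, ΔF, ΔC×SNP, ΔF×SNP. The ΔC×SNP coefficient (β_c) feeds the CE
  category, the ΔF×SNP coefficient (β_f) feeds FE. The ΔTC adjustment
  isolates nutrient-composition effects from total energy intake.
* **Calorie model** (6 terms): Δbodyfat on intercept, gender, age, ΔTC,
  SNP, ΔTC×SNP; the interaction (β_TC) feeds TE.
* **Exercise model** (4 terms): Δbodyfat* on intercept, gender, age, SNP;
  the SNP main effect (β_E) feeds EE.

Inference is finite-sample t (SEs from the unbiased residual variance,
df = n − p), not Wald-z. Fits are complete-case per model; SNPs with fewer
than 5 minor-allele carriers, or monomorphic columns, are skipped with a
logged reason instead of producing unstable estimates. Selection takes the
target term's p strictly below α = 0.05 with no multiplicity correction —
this mirrors the original screening procedure and is a *screening* rule,
not a confirmatory test; a Benjamini-Hochberg flag exists but is off by
default. Selection looks only at the target term, not overall model fit.

## Exercise phenotype Δbodyfat*

The exercise question (1 = no, 2 = yes) is observed at five waves with
uneven missingness. For each pair of consecutive *observed* waves where the
status changed and both body-fat values are present, the oriented
difference is body fat at the "yes" wave minus body fat at the "no" wave;
Δbodyfat* is the per-individual mean of these differences, and individuals
with no usable status change are excluded. The yes-minus-no orientation is
the one consistent with the source cohort's published summary numbers
(starters lose fat, stoppers gain, averaged value ≈ −0.08 kg); it makes the
statistic invariant under time reversal, which the tests assert. Pairs with
unchanged status contribute nothing; a pair with a missing body-fat value
is skipped without dropping the individual. Only consecutive observed waves
are paired — whether an intermediate missing wave should break a pair is
not determinable from the source description, so adjacency among observed
waves is used and documented here.

## LD pruning

LD is the squared Pearson correlation of allele counts over
pairwise-complete individuals (composite LD from unphased genotypes) — the
reference-panel web service the original procedure used has been retired,
so the analysis cohort's own genotypes are the LD source. Pairs with
r² strictly above 0.7 form edges; grouping is by connected components
(deterministic and order-independent, unlike greedy sequential pruning),
and each component keeps exactly its smallest-p member, ties broken
lexicographically by SNP id. r² is treated as the LD score since 0.7 is a
conventional r² cutoff. Pruning is idempotent.

## Scores and classes

Signs: +1 for a positive target coefficient, −1 for a negative one;
reversed for EE because a positive β_E means the allele promotes weight
*gain* on exercise onset. GRS = Σ sign·count is unweighted by design (the
score counts risk alleles; it does not weight by effect size). A missing
genotype contributes its expected count 2·maf rather than zero, so carriers
of missing calls are not biased toward the insensitive end.

Quartiles use linear interpolation between order statistics (position
1 + p(n−1), numpy's default); a nearest-rank (inverted CDF) option is
provided because class boundaries on integer-valued scores move with the
estimator. Class boundaries round upward: a score exactly at the 25th
percentile is L, exactly at the 75th is VH. Cutpoints are computed on the
scored population itself; classifying new individuals against stored
cutpoints is supported explicitly (`build_profiles(..., cutpoints=...)`).
With a degenerate distribution (all quartiles equal) every individual
cascades to VH; single-SNP selections often produce this and should be
treated as uninformative.

## Evaluation

Responder subgroups: for the diet categories, individuals whose intake
change is strictly below the 25th percentile (linear interpolation) of that
change's own distribution — the "greater than the first-quartile reduction"
definition computed from the analysis cohort rather than hard-coded
thresholds, with fixed-threshold overrides possible for strict reproduction
attempts. For EE, individuals with at least one observed no→yes transition.
Class-wise means are raw (unadjusted for gender/age, matching the original
figure's description); a monotone-trend slope — OLS of the individual
outcome on the ordinal class code VL=0…VH=3 within the subgroup — is
reported alongside the means, never replacing them. GRS descriptives
include a Shapiro-Wilk test, run on a seeded subsample of 5 000 when the
population is larger (the test is uninformatively sensitive at large n);
for very large cohorts the test typically rejects exact normality even when
the distribution is visually bell-shaped, and interpretation is left to the
user.

## Synthetic cohort

The generator emulates the data structure of a biannual Korean cohort
survey (n = 8840; dietary questionnaire at baseline and third follow-up,
exercise question at follow-ups 3–7). Defaults are the published marginal
moments:

| quantity | default | unit |
|---|---|---|
| ΔC mean ± SD | −18.4 ± 132.38 | g/day |
| ΔF mean ± SD | −4.71 ± 22.1 | g/day |
| Δbodyfat intercept, residual SD | −0.42, 2.57 | kg |
| age (truncated normal on [20, 90]) | 50.84 ± 8.54 | years |
| baseline carbohydrate / fat / calories | 343.3 / 33.25 / 1960.19 | g, g, kcal |
| baseline body fat | 16.86 ± 5.29 | kg |
| exercise transition probability per wave | 0.4 | — |
| exercise per-pair body-fat noise SD | 2.2 | kg |

ΔTC is built as 4·ΔC + 9·ΔF + noise (Atwater energy factors); the noise SD
defaults to 506 kcal/day so that SD(ΔTC) ≈ √(16·132.38² + 81·22.1² + 506²)
≈ 759 kcal/day, the published marginal. The source tables do not report the
covariances among the three intake changes, so this link is a modelling
convenience that gives the realistic collinearity the diet model's ΔTC
adjustment has to cope with. The 0.4 transition probability comes from the
published per-pair transition counts (≈1350–1400 changes among 3343 per
wave pair).

Genotypes are two summed Bernoulli(maf) draws (HWE), maf uniform in a
configurable range (default 0.05–0.49). LD blocks share the block seed's
maf; each non-seed allele copies the seed allele with probability r and is
redrawn otherwise, making the expected genotype correlation equal r.
Missingness is MCAR at a configurable rate (default 0).

Planted effects enter the linear predictor exactly as the fitted models
expect them (β·Δ·count for CE/FE/TE; for EE, each status change increments
body fat by ±Σβ·count according to direction), so zero-noise cohorts allow
machine-precision recovery checks. Gender/age coefficients on Δbodyfat
default to 0 — the source reports no covariate effect sizes, and null
covariates keep type-I calibration clean — but are configurable. Baseline
levels are lifted minimally where needed so all emitted levels stay
positive while the drawn deltas are preserved exactly.

What the generator does *not* emulate: questionnaire measurement error and
recall bias, item-level dietary composition, population stratification and
relatedness, informative missingness, and secular trends across waves.
Passing tests therefore demonstrate the statistical machinery is correct
under the assumed model, not that the screen is robust to those real-data
complications.

## Numerical conventions and determinism

All randomness flows from `numpy.random.default_rng` seeded per
(seed, substream), so identical configurations are bit-reproducible;
genotypes, diet outcomes, exercise series and covariates use separate
substreams and the covariate stream is shared between the diet and exercise
generators so both sub-studies describe the same people. Tables are written
as tab-delimited UTF-8 with `NA` for missing and shortest round-trip float
formatting, and read back with round-trip float parsing, so a
write-then-read cycle is bit-exact and `run-all` is byte-deterministic.
Rank-deficient designs raise an error naming the collinear columns.
Exactly-zero coefficients have no defined sign and raise. Gender is coded
0 = male, 1 = female in the file format (the source never states its
coding; one convention had to be frozen).

## Problem sizes used by tests and the acceptance script

Oracle-equivalence fixtures use n = 300; type-I calibration uses 2000
individuals × 1000 SNPs; power/sign-recovery uses 200 replicates at
n = 4000 with effects at the published top-SNP magnitudes (β_c = 0.006,
β_TC = 0.00056, β_E = −0.14) and residual SD 2.57 kg; end-to-end
monotonicity uses 50 replicates at n = 10⁴ with a 16-SNP panel and three
planted SNPs per category. These sizes give the simulations comfortable
power while keeping a full run on one CPU in minutes; they are the
package's documented study conditions, not tuning knobs.

## Known limitations

* The selection rule reproduces the original raw-α screen; at α = 0.05
  over hundreds of SNPs a material fraction of selections are false
  positives, which the unweighted GRS partially averages out but does not
  remove.
* Classes from single-SNP (or empty) selections are degenerate (everyone
  VH) and should be ignored; the pipeline logs this but does not refuse.
* Cutpoints learned on small cohorts are noisy; classifying new individuals
  against them inherits that noise.
* The trend statistic treats class as equally-spaced ordinal; it is a
  summary of monotonicity, not an effect-size model.
* Total calorie intake is treated in kcal/day throughout; the source
  labels one table's calorie rows "(g)" but discusses kcal elsewhere, and
  the format here fixes kcal.
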