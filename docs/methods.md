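# Methods

## The model

The outcome is the LQrv raw score of the Questionnaire of Olfactory
Disorders' life-quality statements: 17 negative statements scored
agree→3 … disagree→0 and 2 positive statements scored in mirror image,
summed to LQrv ∈ [0, 57] (higher = worse smell-related quality of life).

Nine prognostic factors enter an ordinary least-squares model
X = b₀ + Σ bⱼxⱼ:

| factor | meaning | scale |
|---|---|---|
| x₁ | MTHFR class score | integers 0–4 |
| x₂ | phase II class score | integers 0–18 |
| x₃ | phase I class score | integers −2–10 |
| x₄–x₇ | compounds exposure, psychological trauma, physical trauma, previous surgery | 0 absent / 1 present |
| x₈ | age | years |
| x₉ | gender | 0 male / 1 female |

The class scores are additive composites over a fixed variant registry
(2 MTHFR + 5 phase I + 10 phase II scoring entries). The grouping
follows the modelled study design verbatim, including its
counterintuitive placements (UGT1A1*28 inside phase I; the antioxidant
enzymes SOD2/CAT/OGG1/PON1/NOS3/MPO inside "phase II"). Per-variant
encodings: gene dose 0/1/2 for biallelic SNPs and the UGT1A1 TA-repeat
(alleles with ≥7 repeats count as *28-like mutants, so 7/8 genotypes
score 2); 0/1 for GSTM1/GSTT1 presence/deletion ("null" is homozygous
deletion — the multiplex assay cannot see heterozygotes); and for
CYP2D6/CYP2C19 the diplotype is translated to a metabolizer phenotype
scored UM → −1, EM → 0, IM → 1, PM → 2.

### Phenotype translation

CYP2D6 uses per-allele function assignments (*1/*2/*2A functional,
*2xN increased, *10/*41 reduced, *4/*6 null) combined by a symmetric
pair rule: any increased allele → UM; otherwise any functional allele →
EM; reduced/reduced or reduced/null → IM; null/null → PM. The
"increased dominates" choice covers duplication diplotypes for which no
published combination rule exists. CYP2C19 is handled by a per-gene
diplotype override table (default *1/*1→EM, *1/*2→IM, *2/*2→PM,
*1/*17→UM, *17/*17→UM, *2/*17→IM) because the conventional clinical
translation of a single loss-of-function allele (IM) differs from the
naive function-pair rule (EM); the override table is configurable, so
any alternative convention can be swapped in.

## Regression report

Fitting is delegated to statsmodels OLS; the report adds standardized
coefficients βⱼ = bⱼ·sd(xⱼ)/sd(y) (n−1 sample SDs), partial correlations
rⱼ = tⱼ/√(tⱼ² + df) with df = n − 10, two-sided p-values and 95% CIs from
the t distribution with the same df, multiple R = √R², and a Pareto
ranking of |t| against the two-sided critical value at α (default 0.05;
≈ 2.0281 at 36 df). Both β and partial r are always reported because the
two are easily conflated in published tables. No multiple-comparison
correction is applied — deliberately, matching the exploratory design —
and every report carries an explicit caveat string saying so.
Residual diagnostics (D'Agostino K² normality; Levene's test between
residual halves split at the median fitted value) are advisory only and
are skipped below n = 8.

## Desirability profiling

The published profile tables are reproduced exactly by a two-sided
piecewise-linear transform through (low, 0), (center, 0.5), (high, 1),
clamped outside; defaults low = 22, high = 40, center = the cohort mean
prediction (the transform was identified by verifying it against every
published profile row; it is a replaceable strategy). Note the inverted
semantics: because the study frames profiling as *risk* identification,
higher predicted impairment maps to higher "desirability"; d measures
progress toward the high-impairment end of the band, not benefit.

Profiles evaluate one factor at mean + k·SD (k = −2..2, sample SDs,
constant spacing) with all other factors at their means; binary factors
are profiled on the same continuous grid (levels like 1.53 are
intentional). The center row of every profile therefore predicts the
cohort mean (≈ 28.674) at d = 0.5. Global desirability is the geometric
mean of partial values (zero annihilates). Cut-off search inverts the
single-factor prediction in closed form,
level = mean + (target − center)/bⱼ, for positive-coefficient factors,
flagging levels outside the ±2·SD grid as unreachable; at
target = center every cut-off is the factor's own mean (phase I 1.5,
phase II 5.85, compounds 0.52, surgery 0.30).

Numerical note: with the published coefficients printed to five
decimals, predictions reproduce the published grid to ~2×10⁻⁴ (the age
coefficient's print rounding alone contributes up to 2.4×10⁻⁴);
desirabilities reproduce to <5×10⁻⁶ because the center offset cancels.
The package's own computed center (28.674079) is used as the anchor
rather than the printed 28.67391.

## Frequency analysis

Genotype percentages and gene-dose allele frequencies per variant;
metabolizer phenotype fractions per gene. Reference comparisons build a
2×2 table [[k, n−k], [round(p_ref·n_ref), n_ref − round(p_ref·n_ref)]]
(half-away-from-zero rounding for determinism) and use the two-sided
Fisher exact test (minimum-likelihood rule, via scipy). Published
reference comparisons cannot be reproduced exactly because reference
cohort sizes were not printed; `n_ref` is therefore an explicit input,
defaulting to 1000 with a logged warning. Both genotype-level and
allele-level margins are available, since published tables do not state
which was used.

## Synthetic cohort generator

Defaults restate the published cohort: n = 46; biallelic genotypes drawn
under Hardy–Weinberg at the published cohort allele frequencies;
deletion genotypes Bernoulli at the published null fractions; CYP2C19
diplotypes from its published allele frequencies; age Gaussian
(47.24 ± 10.06, truncated to [18, 90]); female probability 27/46;
binary events at prevalences 24/46, 17/46, 14/46, 14/46; outcome =
published linear model + N(0, σ_res), rounded to an integer and clamped
to [0, 57], with the pre-rounding latent value retained for recovery
tests. σ_res defaults to 4.22·√(1 − 0.88²) ≈ 2.00, derived from the
published outcome SD and multiple R. Questionnaire sheets can be
attached by inverting the scoring (points distributed randomly over
items), so scoring the sheets reproduces the generated LQrv exactly.

Two choices had no published value and were fixed once:

* CYP2D6 allele frequencies (only phenotype fractions were published):
  defaults approximate the published PM/IM/EM/UM mix ≈ 6.5/6.5/80.5/6.5%
  under Hardy–Weinberg.
* Direct-score mode draws the nine factors directly — integer-rounded
  Gaussians (clipped to the legal class-score ranges) for x₁–x₃,
  Bernoulli for the binaries, Gaussian age — matched to the published
  factor means and SDs. This mode exists for regression-focused
  experiments where the factor moments, not the genotype mechanism,
  matter.

The published summaries are internally inconsistent in two places the
generator must navigate: the profiler's psychological-trauma center
level (0.5217) duplicates the compounds-exposure level and contradicts
the prevalence table (17/46 = 0.3696). Genotype mode follows the
prevalence table; direct-score mode follows the profiler's factor means,
as its contract states. Neither is "corrected".

### What a green test does and does not establish

The generator draws variants and factors independently. Real cohorts
have predictor covariance, and the published cohort demonstrably did:
with independent predictors at the published factor SDs, the signal
variance implied by the coefficient vector is Σ(bⱼ·sdⱼ)² = 6.21, giving
population multiple R = √(6.21/(6.21 + 2.00²)) ≈ 0.78 — the published
R = 0.88 with outcome SD 4.22 requires signal variance ≈ 13.8, i.e.
substantial positive predictor covariance (plus small-sample inflation
at n = 46) that no published table quantifies. Synthetic-cohort R
therefore concentrates near 0.78, not 0.88, and tests of R against the
published value are expected to fail under the stated independent world;
coefficient recovery, mean-outcome reproduction and all deterministic
artifacts are unaffected. The generator also omits linkage (the two
CYP2C9 sites are drawn independently despite the published 10.9%
compound-heterozygote figure), population stratification and missing
data.

## Degenerate inputs and tie-breaks

Missing genotypes are hard errors unless `missing_as_wildtype=True`
(scored 0, logged) — silent imputation would bias class scores downward.
Incomplete questionnaire sheets are rejected, not prorated. Constant or
collinear design columns raise a named rank error rather than silently
dropping a predictor; a constant outcome is rejected (R undefined).
Gender accepts only the binary 0/1 coding the model defines. Pareto
ordering is a stable sort on |t|, so exact ties keep the canonical
factor order.
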