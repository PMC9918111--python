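# Methods

## Generative model (synthetic cohorts)

Exposure liability for participant *i* is

    L_i = G_i + c·U_i + ε_i,   G_i = Σ_k b_k g̃_ik,

where g̃ are standardised dosages, the polygenic coefficients b_k are
rescaled on the realised sample so Var(G) = h², U is a standard-normal
latent confounder with loading c (`confounder_beta_exposure`), and
ε ~ N(0, 1 − h² − c²) so Var(L) = 1. The exposure indicator is
1{L_i > τ} with τ = Φ⁻¹(1 − K) for target prevalence K; because the
liability is standardised on the realised sample, the realised prevalence
is binomially tight around K (the simulator enforces a 3-SE check).

Each outcome is Bernoulli with

    logit P(Y_i = 1) = α + β_causal·k·L_i + β_conf·U_i + Σ_j δ_j g̃_ij,

where k = φ(τ)/(K(1−K)) is the standard liability-to-log-odds conversion
at prevalence K. Multiplying the liability by k makes `causal_beta` read
directly as *outcome log-odds per unit exposure log-odds* — the scale on
which Wald ratios and the per-doubling transform operate. The intercept α
is solved numerically (Brent) so the mean outcome probability equals the
configured baseline prevalence; configurations whose effects saturate the
probabilities are rejected with the offending outcome named. The δ_j terms
plant horizontal pleiotropy (balanced, directional, or single-outlier
depending on the map supplied).

Genotypes come from a haplotype-sharing copula: variants in an LD block
share one allele frequency, and on each of two haplotypes a variant copies
the block's shared latent uniform with probability √ρ, giving pairwise
dosage correlation ≈ ρ (`ld_rho`) within blocks and independence across
blocks. Palindromic variants are created as A/T or C/G pairs and a
configurable fraction receives an allele frequency in 0.42–0.50 so the
harmonization filter is exercised. Diagnosis records carry uniform random
dates over a configurable window; a small fraction is emitted in ICD-9
through a built-in toy equivalence mapping, and exclusion conditions are
planted in a configurable sliver of the cohort.

All randomness derives from one master seed through
`numpy.random.SeedSequence` children, one per component, so datasets are
bit-reproducible and insensitive to the order in which components are
extended.

### What the simulator does and does not emulate

It reproduces the statistical structure the analysis relies on: liability
threshold exposure with polygenic architecture, confounding through a
shared latent variable, configurable horizontal pleiotropy, block LD,
intermediate-frequency palindromic variants, partial ascertainment through
four overlapping criteria, and dated exclusion conditions. It does **not**
emulate realistic human LD maps, relatedness/kinship (cohorts are
unrelated by construction, which is why the GWAS uses plain covariate-
adjusted logistic regression rather than a mixed model), imputation
uncertainty, X-chromosome dosage rules, or feedback loops (an outcome
cannot causally influence the exposure, so genuinely bidirectional
cohorts cannot be generated — bidirectional behaviour is tested at the
summary-statistics level instead). Passing tests therefore demonstrate
correctness of the estimators and plumbing under these idealised
conditions, not performance on real biobank data.

## Phenotype construction

Codes are normalised (dots stripped, upper-cased) before any comparison.
"More than 250 cases" is implemented strictly (`case_count > min_cases`,
default 250). The chapter whitelist keeps ICD-10 letters A–O and Q
(chapters I–XV and XVII), excluding perinatal codes, symptoms/signs,
injury/poisoning and the supplementary chapters. Exposure exclusion uses
the rule: an exclusion diagnosis dated on or before the earliest exposure
diagnosis excludes the participant; a participant with an exclusion code
but no dated exposure diagnosis is excluded conservatively (the timing
cannot be established). This tie/undated handling is a design choice —
the natural-language rule "before diagnosis" does not determine it.

## Association scans

Per-variant and per-phecode logistic regressions use an in-package IRLS
Newton solver (Fisher scoring, max 100 iterations, tolerance 1e-8, Wald
tests) warm-started from the covariate-only fit; monomorphic variants are
emitted with an NA record and separated/non-converged fits are flagged,
never fatal. The solver is cross-checked against `statsmodels.Logit` in
the test suite. The GWAS covariate default is age, sex and 10 principal
components; the PheWAS additionally adjusts for assessment center.

## Polygenic scores

Clumping is greedy by ascending p (ties: smaller SE, then lexicographic
id, making output order-independent), removing every variant within the
window whose r² with the retained lead reaches the threshold; r² comes
from in-sample genotypes. Two presets exist because score construction
and instrument selection use different stringencies: the PRS preset
(r² < 0.1, 250 kb, p < 0.05) and the instrument preset (r² < 0.001,
10,000 kb, p < 1 × 10⁻⁵). The score-construction settings behind a
specific published score are generally unstated, so they are plain
configuration here. Missing dosages are mean-imputed per variant. Scores
are standardised to mean 0 / SD 1 on the scored set; scaling constants are
returned so base-sample standardisation can be applied to held-out
samples.

## Two-sample MR

*Harmonization.* Outcome effects are aligned to the exposure effect
allele: swapped alleles flip the sign and complement the frequency;
strand relabelling (A↔T, C↔G) is tolerated; anything else is dropped with
reason "incompatible alleles". Palindromic variants with exposure allele
frequency in [0.42, 0.58] (inclusive) are excluded as strand-unresolvable;
outside the band they are aligned by frequency side. A
`strict_eaf_exclusion` switch applies the band to *every* variant — the
literal reading of the filter — while the default restricts it to
palindromic variants, the conventional reading; both are one flag apart.

*Estimators.* Wald ratio with first-order delta SE (σ_Y/|γ̂|); IVW as the
inverse-variance weighted mean of ratios, fixed-effect SE (Σw)^(−1/2) or
multiplicative random effects (SE inflated by max(1, √(Q/(m−1)))) —
`ivw_auto` reports random effects when Cochran's Q has p < 0.05, the
fixed-effect form otherwise, and both always appear in the suite output.
MR-Egger is a WLS of Γ̂ on γ̂ with intercept and weights 1/σ_Y², after
re-orienting instruments so γ̂ ≥ 0 (the estimate is not orientation-
invariant; this is the standard convention); its residual variance factor
is never deflated below 1. The weighted median interpolates the
inverse-variance cumulative weight function at 0.5; the weighted mode
maximises a weighted normal-kernel density with bandwidth =
`bandwidth_factor` × 0.9·min(sd, iqr/1.34)·m^(−1/5) on a 2048-point grid;
both get parametric-bootstrap SEs (default 1000 seeded draws of (γ̂, Γ̂)
from their normal errors). Estimates are reported per doubling of
exposure odds using the literal constant 0.693 (an `--exact-ln2` CLI flag
switches to ln 2).

*Steiger.* For binary traits the per-instrument variance explained is
approximated by r² = Z²/(Z² + n); direction is decided by the summed r²
and the p-value by a two-sided z-test on the difference of Fisher-
transformed aggregate correlations. The binary-binary variant of this
test is not standardised; this approximation is the documented choice.

*MR-PRESSO.* Observed global RSS uses leave-one-out IVW predictions with
weights 1/σ_Y²; the null is built from parametric draws
Γ* ~ N(β̂₋ⱼγ̂ⱼ, σ_Yⱼ) (default 1000, seeded) with the +1-corrected
empirical p so p ≥ 1/(n_sim+1). Per-instrument outliers are two-sided
empirical p-values of each observed residual against its own simulated
distribution, Bonferroni-adjusted by m. When outliers are found the IVW
estimate is recomputed without them; the distortion coefficient is
100·(β_corrected − β_all)/|β_corrected| with a resampling p from 1000
random same-size subsets.

## One-sample MR

Two-stage predictor substitution: stage 1 is a logistic regression of the
exposure indicator on the scaled PRS plus covariates; its linear predictor
(fitted exposure log-odds) replaces the exposure in the stage-2 logistic
regression of the outcome. Stage-2 Wald SEs are reported without a
generated-regressor correction (a seeded participant bootstrap is
available). Note an intrinsic property of this estimator under a
liability-threshold exposure: marginalising the outcome's logistic model
over the non-genetic liability components, and approximating a
probit-type exposure link with a logistic stage 1, attenuates the
coefficient relative to the planted liability-scale effect (≈20% at the
default settings). The recovery test therefore checks coverage of the
estimator's own large-sample limit, computed from an independent large
simulated cohort, alongside sign recovery and the confounding-robustness
contrast (two-stage CI covers the null where the crude logistic estimate
is decisively confounded).

## Power

power = Φ(ncp − z₁₋α/₂) + Φ(−ncp − z₁₋α/₂) with
ncp = |ln OR|·√(n·r²·f(1−f)); the second term matters only near the null,
where it restores the two-sided size. The formula is validated against a
Monte-Carlo oracle (individual-level simulation with an instrument
explaining r² of the exposure, logistic Wald test) within ±0.03.

## Pipeline

GWAS runs in the base half only; PRS, PheWAS and one-sample MR in the
target half only, mirroring the overlap-avoiding split design. Two-sample
MR uses base-half exposure statistics with outcome statistics scanned in
the full analysis set by default (`outcome_scan="full"`), matching a
design where outcome scans come from the whole cohort; `"target"`
restricts them to the target half. Pleiotropy pruning uses the other
significant phecodes' scans as secondary traits at threshold 0.05/665.
Sex-stratified runs drop the stratum variable from the covariates and
recompute the Bonferroni K within stratum. The run manifest records every
seed, threshold and filter count; a double-run hash test verifies that
identical manifests give identical outputs.

## Problem sizes in tests and the acceptance script

Calibration suites run at the scale their Monte-Carlo error requires:
IVW type-I/coverage over 500 replicates of 80 instruments (F ≈ 20–50,
matching the strength range typical of relaxed-threshold instrument
sets); robustness over 200 replicates with a 30% invalid minority;
MR-PRESSO detection over 100 replicates with a 10σ planted outlier;
Steiger over 100 forward/reverse pairs. End-to-end recovery uses
replicate 20,000-participant cohorts with 240 variants (30 causal,
h² = 0.25), one causal outcome (β = 0.5 per doubling-compatible unit)
among null outcomes and background phecodes — a deliberately scaled-down
phenome that keeps each replicate's GWAS exact rather than approximated.

## Known limitations

- No relatedness correction (and none needed for the simulated cohorts).
- In-sample LD only; no external reference panels.
- No correlated-instrument or multivariable MR, no colocalization.
- Two-stage SEs ignore the generated regressor unless bootstrapped.
- The reverse-direction and bidirectional analyses are exercised on
  summary statistics and on mediated-instrument cohorts; true feedback
  cycles cannot be simulated at the individual level.
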