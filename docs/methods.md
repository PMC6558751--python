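# Methods

## Scope and data model

The package implements the pruning + thresholding + metaGRS workflow for a
binary disease with registry follow-up: construction of per-sample genetic
risk scores from GWAS summary statistics, selection of the best p-value
threshold on a prevalent case-control training set, combination of component
scores into a metaGRS, and survival evaluation of the result on the incident
part of the cohort. Because the cohorts such analyses run on are
access-restricted, a synthetic biobank generator is part of the package
proper: the generator defines the study conditions under which every claim
in the test suite is made, and this note records what it does and does not
emulate.

## Synthetic biobank generator

**Genotypes.** Dosages follow a latent-Gaussian copula per LD block. Each
haplotype's latent vector is equicorrelated within a block; the latent
correlation is solved (Brent's method on a Gauss–Legendre evaluation of the
bivariate normal CDF) so that the mean pairwise correlation of the
*thresholded alleles* across the block's MAF pairs equals the requested
`within_r` — the quantity the r² pruning filter operates on. Two independent
haplotypes sum to the dosage, blocks are independent, and MAFs are uniform
on a configurable range (default 0.05–0.5). This gives direct control of the
r² structure at the cost of realism: real LD decays with distance and real
blocks are neither equicorrelated nor independent, so passing tests say
nothing about haplotype-level phenomena (imputation quality, long-range LD,
population structure).

**Effects.** A configurable number of causal variants receive N(0,
effect_sd²) per-allele weights. When a target hazard ratio per score SD is
requested, weights are rescaled so the raw score's SD equals log(HR); a
target of 1 therefore yields exactly zero weights, which is the package's
null model.

**Onset and follow-up.** Disease onset is proportional hazards on the age
timescale: Λ(a|η) = (a/b)^k · e^η with η the centered true score. The shape
is k = 3 by default — cause-specific incidence rising roughly with the
square of age, which is what premenopausal breast-cancer registry curves
show. A steeper default (k = 4) was considered and rejected: it compresses
the age axis so much that the top-5% stratum would reach the population's
age-70 risk only ~14 years early, whereas the observed pattern this class of
analysis reports is a 15–20+ year lead; the shape is a constructor argument
for anyone wanting a different baseline. The scale b is solved numerically
(Brent) so the population cause-specific cumulative incidence at age 70 —
evaluated semi-analytically by integrating h₀(a)e^η exp(−Λ(a|η) − Λ_d(a))
over an age grid and averaging over a subsample of η — equals a target,
5.1% by default. Competing mortality is Gompertz, rate(a) = 1e-5 · e^{0.1a},
approximating female all-cause mortality (≈1.5/1000 at 50, ≈11/1000 at 70).
Entry ages are uniform on 30–70; per-subject administrative censoring is
entry + U(4, 13) years capped at age 85, emulating a recruitment window of
several years linked to registries at a fixed later date. None of these
defaults claims to match any particular cohort's follow-up distributions;
all are configurable. Subjects dead before entry are excluded (left
truncation); subjects with onset at or before entry are retained flagged
`prevalent`, since the workflow needs them for its case-control training
set.

**Covariates.** Family history is 0/1 with logit(P) = logit(0.08) + 0.35·z
(z the standardized true score), plus a third "unknown" level drawn at 15% —
modest values reflecting that a first-degree family history is both
uncommon and only partially explained by common variants. The clinical
absolute-risk covariate is a toy Gail-style function of entry age, age at
menarche, age at first birth and family history with lognormal noise — by
construction independent of genotype given family history, which is exactly
the property the adjusted Cox models and interaction tests need to be
interpretable. Reproductive covariates, BMI, smoking, menopause age and four
principal-component columns are drawn from plausible marginals without any
deeper dependence structure.

**Summary statistics.** Per-variant estimates are the true log-OR effect
plus Gaussian noise with the analytic case-control standard error
SE = 1/√(2f(1−f)·N·φ(1−φ)); p-values are two-sided Wald. Linear-scale output
multiplies both estimate and SE by φ(1−φ), making the provided
linear→log-OR transform its exact inverse. The analytic-SE choice keeps
generation O(variants); it ignores the correlation of estimates across
LD-linked variants that a real discovery cohort would induce.

## Score construction

Pruning is greedy clumping: candidates in ascending p-value order (ties by
chromosome, position, id — deterministic), accepted iff r² with every
already-accepted variant within 1 Mb on the same chromosome stays ≤ 0.1,
with r² computed on the analysis panel's own dosages. Zero-variance variants
are excluded (r² undefined). Thresholding produces one weight set per cutoff
of a strictly increasing grid; the default grid has 22 cutoffs from 5e-8 to
1.0, giving 44 candidates for two summary sources. Filtering uses p ≤ cutoff.
Scores are plain weighted dosage sums; missing dosages contribute 2·AF·β
(PLINK-style mean imputation) or zero under the `drop` policy, without
renormalization. Standardization moments are always computed on a declared
reference sample set and stored so they can be re-applied to held-out
samples.

## Training

Threshold selection fits one age-adjusted logistic model per candidate on
the training set and takes the smallest p-value; non-converged or separated
fits are flagged and cannot win. Equal candidates (nested thresholds that
admit no new variant) tie, and the stable sort resolves ties toward the
tighter threshold. metaGRS weights are **marginal** log ORs per SD — one
age-adjusted model per component — following the original metaGRS
construction; a joint-model alternative sits behind `joint=True`. Membership
of the smaller combinations (top-3, top-2) is ranked by incident-disease
association (cause-specific Cox p-value on the age timescale) via
`rank_components`, with the prevalent-logistic ranking available by calling
`select_best_threshold` instead; the combined score is restandardized on the
reference set, which makes the combination invariant to rescaling all
weights. The analytic power curve uses the two-sided Wald approximation
SE ≈ √(1/n_cases + 1/n_controls), exact at the null (power = α at OR 1).

## Survival evaluation

Cox fits are cause-specific partial likelihood with Efron ties (lifelines
backend), competing deaths censored. The age timescale uses (entry, event]
risk intervals; zero-length intervals are perturbed by +1 day to keep the
subject in a risk set (logged). The follow-up timescale starts every subject
at 0 — used for per-SD effects and concordance when an age-bearing clinical
covariate is in the model. Wald 95% CIs throughout.

Harrell's c is computed by a sweep over event times with a Fenwick tree on
dense risk ranks, O(n log n), honoring delayed entry (a pair is comparable
when the failing subject's event time falls inside the other's at-risk
window); tied risks count ½, tied event times are not compared. The sweep is
property-tested against the O(n²) pairwise definition with ties, censoring
and truncation.

The Aalen–Johansen estimator is implemented directly: risk sets are
{entry < t ≤ exit}, the all-cause product-limit survival multiplies through
every event time, and cause-specific increments S(t⁻)·d_c/Y accumulate the
CIF. By construction CIF₁ + CIF₂ + S = 1 at every jump (the test tolerance
is 1e-10). Pointwise 95% CIs use an Aalen-type variance Σ S(t⁻)²·d_c(Y−d_c)/Y³
on the log scale; the covariance terms between jumps are omitted, so the
bands are mildly approximate — adequate for the descriptive plots and the
age-at-risk-level readouts they support. With delayed entry the estimator is
consistent for the unconditional CIF only above the earliest entry age;
since nothing is observed before age 30, population estimates at 70 sit a
few tenths of a percentage point below the generative target (≈0.4 pp under
the default shape), which the calibration tests' tolerances reflect.

Strata are named percentile intervals with cutpoints as empirical quantiles
(NumPy linear interpolation) of the analysis sample, half-open [lo, hi)
except the top interval; assignment is first-match-wins, relevant only under
heavy ties. Attenuation of an exposure after adjustment is reported on the
ratio scale, 100·(R_u − R_a)/R_u, with a log-scale flag. Interaction tests
are Wald p-values on a product term after an explicit collinearity check
(least-squares residual of the product on the main effects). The
cross-classification report counts samples that are high (≥ a percentile
cut) in exactly 0–3 of three scores plus pairwise overlaps. Association
scans dispatch on the declared covariate type — linear, logistic, or
cause-specific Cox for event indicators — and append Benjamini–Hochberg
q-values per scan as labelled hygiene; the primary estimates are unadjusted.

## Pipeline

`run_pipeline` executes simulate → build-scores → select → combine →
evaluate, writing every intermediate as tab-delimited text plus a JSON
manifest of parameters, derived seeds and SHA-256 file hashes. All
randomness derives from one seed via hashed labels, so a rerun reproduces
every artifact bit for bit and a deleted intermediate is regenerated
identically. Failures abort with the stage named; partial outputs are kept.
The published multigenic scores of the demo configuration are emulated as
the largest true effects observed with 30% relative weight noise — a
synthetic stand-in, not a transcription of any published score.

## Problem sizes

Module tests run at desk scale (hundreds to tens of thousands of samples);
the consistency suite uses 200,000-woman replicates (three in the tests,
five in `scripts/acceptance.py`) for the strata hazard ratios, cumulative
incidences and concordance, 500 replicates for Cox CI coverage, 5,000
replicate logistic fits for the power-curve oracle, and five seeds of
100,000 validation samples for the metaGRS-vs-component comparison.

## Limitations

Real LD maps, imputation error, population structure, X-chromosome dosage,
genome-build liftover and INDELs are out of scope. The generator's
covariate dependence structure is deliberately minimal; association-scan
results on synthetic data exercise the machinery, not epidemiology. Only
one competing event (death) is modelled, subdistribution (Fine–Gray)
regression is not provided, and the metaGRS is a fixed two-stage
train/validate procedure — no cross-validation or penalized weighting.
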