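# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generators do and do not emulate.

## Polyploid genotypes and clonal clustering

**Dosage and filtering.** Genotypes are read from VCF 4.x with a fixed ploidy
(default 3); the dosage of a call is its count of alternate alleles, and any
partially missing call is treated as missing. Site-level filtering applies six
strict inequalities on freebayes-style annotations — QUAL > 1, QUAL/AO > 10,
SAF > 0, SAR > 0, RPR > 1, RPL > 1 — rejecting (never silently keeping)
records that lack an annotation. The final SNP set keeps biallelic,
polymorphic loci with MAF ≥ 0.15 and a mean per-sample read depth in
[10, 1000]. MAF is computed on allele counts, `f = Σd / (ploidy · n)`,
`MAF = min(f, 1 − f)`; a locus where every sample has the same heterozygous
dosage therefore has a nonzero MAF but is removed by the polymorphism rule.
The MAF comparison at the boundary uses ≥.

**Identity by state.** Pairwise similarity is the mean over
pairwise-complete loci of `1 − |dᵢ − dⱼ| / ploidy`. This is the natural
dosage generalization of diploid IBS and equals the maximal fraction of
alleles shared between the two unordered allele multisets (proven against a
brute-force multiset oracle in the tests). For ploidy 2 it reduces to the
standard diploid formula. Pairs with no shared non-missing loci get a missing
entry plus a warning. Clustering runs agglomeratively on 1 − IBS; the default
linkage is UPGMA (average), the common choice for SNP IBS dendrograms, and the
cluster count is always user-supplied (`cut(k)`) — no automatic k selection.
PCA mean-imputes missing dosages per locus, mean-centers by default, and
optionally scales to unit variance; variance explained is reported in percent
of total.

**Genome-wide rescaling.** A SNP-set dissimilarity fraction is converted to
an implied SNP count (`round(fraction × n_snps)`) and a genome-wide percent
(`100 × count / genome_size`, default 2 decimal places).

## Closed respirometry

**Rates.** The consumption rate of a well is the positive magnitude of the
OLS slope of O₂ (% air saturation) against time (h), by default over the full
trace. Film diffusion is the mean rate over the sealed no-animal wells of a
separate run and is applied batch-wide; microbial background is computed per
run from that run's blank wells. Because blanks are sealed wells too, their
measured decline already contains diffusion, so the pipeline subtracts
`blank_rate − diffusion` as background before the generic correction
`corrected = raw − diffusion − background`. Negative corrected rates are kept
but flagged. Mass-specific rates divide by allometric dry weight
(a · length^b with a = 9.015362, b = 2.86448, length in mm).

**Batch standardization.** The per-run bias of the reference clone is
`|mean(ref, run) − mean(ref)| / mean(ref)` with the overall mean pooled over
all reference measurements. Two standardization modes exist: `ratio`
(default) multiplies each mass-specific rate by `mean(ref) / mean(ref, run)`,
which by construction equalizes the reference clone's run means and preserves
units; `literal` multiplies by the dimensionless bias itself. The literal
form is retained because it is one published reading of the procedure, but it
collapses the rate scale and is not the default.

**P_crit.** The critical oxygen limit is estimated from a rate-vs-O₂ profile
(either supplied directly or built from rolling-window OLS slopes over a
trace, default 10 points per window) by a broken-stick fit: an exhaustive
search over every interior breakpoint leaving at least `min_segment`
(default 3) points per side, independent OLS lines on each side, and the
breakpoint minimizing total RSS. P_crit is the O₂ at the intersection of the
two lines, falling back to the breakpoint observation's O₂ when the lines are
parallel or the intersection leaves the observed O₂ range. An animal is coded
as having reached P_crit iff the two-segment fit beats the single line by an
extra-sum-of-squares F test (2 numerator df, n − 4 denominator df, default
α = 0.05) *and* the segment slopes are genuinely distinct; degenerate inputs
return reason codes (`insufficient_data`, `no_breakpoint`) instead of
raising. Noiseless fixtures are handled exactly (RSS ≈ 0 short-circuits the
F statistic to ∞ or the fit to "no breakpoint" if a single line is already
perfect).

## Thermal tolerance

T_imm records enter at the individual level; video analysis is upstream and
out of scope. Exclusions run in a fixed order: males, egg-bearing females,
whole clones left with fewer than `min_replicates` (default 3) records, then
a seeded uniform without-replacement subsample of the reference clone to
`reference_n` (default 6). The subsampling mechanism is an assumption (the
procedure is only described as "random"). Exclusions are idempotent and fully
logged (kept + logged = input). Ramp schedules are discrete
(time, temperature) tables — 1 °C per 6 min from 18 °C for CT_max
determination, and an 18→34 °C/16 min pre-assay ramp whose mean slope is
1 °C/min; CT_max is the ramp temperature at which the last animal
immobilized, and the assay temperature helper is CT_max − 2 °C.

## Environmental model chain

Two univariate regressions are shipped as configurable `LinearModel`s:
ice-out day = −2.33 · MayT + 165.24, and July water temperature =
−0.1018 · IoD + 3820.4. The second intercept, as printed in its source,
yields non-physical temperatures (~3805 °C at IoD 150) and is inconsistent
with the accompanying 11.04–13.77 °C range for IoD 141–170; it is shipped
literally (with a 0–25 °C plausibility guard that flags every prediction)
alongside a recalibrated variant anchored to the published extremes
((141, 13.77), (170, 11.04)). Neither is asserted to be the original
encoding; users can supply their own coefficients. Day-of-year is an integer
with no leap-year adjustment.

## Mixed models and comparisons

**Gaussian LMMs.** Models with crossed random intercepts (experimental run;
clone nested in genetic cluster or subpopulation, materialized as combined
labels) are fitted by a profiled likelihood: the marginal covariance is
σ² (I + Σ γ_k Z_k Z_kᵀ), β and σ² are profiled in closed form, and the
likelihood is maximized over log variance ratios with multi-start
Nelder-Mead. Sample sizes in this design (~100–150 rows) make the dense
Cholesky per evaluation trivial, and the direct search avoids the
local-optimum failures that iterative variance-component solvers exhibit on
near-boundary fits; the fitter reproduces lme4's lmer ML and REML
log-likelihoods to ~1e-6 (checked in the test suite via Rscript). Parameter
count is n_fixed + n_variance_components + 1 (residual); deviance is
tabulated as −2·logLik; AIC = −2·logLik + 2·npar and BIC uses log(n).
Models with no random terms fall back to OLS (where ML and REML point
estimates coincide).

**Binomial GLMMs.** The probability of reaching P_crit is modelled with
Bernoulli-logit mixed models fitted by a Laplace-approximation maximum
likelihood written here (no ML GLMM exists in the installed Python stack):
the random-effects mode is found by damped Newton iterations and the Laplace
objective `ℓ(u*) − ½ u*ᵀD⁻¹u* − ½ log det(D ZᵀWZ + I)` is maximized over
(β, σ) with Nelder-Mead plus a BFGS polish. This matches lme4's default
glmer (nAGQ = 1) objective; agreement to ~1e-4 in log-likelihood is verified
in the tests. REML is undefined for this family and is rejected.

**Selection and reporting.** Nested ML fits are compared by likelihood-ratio
tests (χ² = deviance_null − deviance_full, df = Δnpar); the fuller model is
selected only when p < 0.05, ties resolving to the simpler model. Selected
Gaussian models are refitted with REML for reporting — effect estimates and
their SEs should be read from the REML fit, since ML variance components are
biased low at ~20 clones and ML-based intervals undercover. If the optimizer
fails outright on a model containing the clone random effect, the model is
refitted without it, and `compare_models` then reruns the whole set without
the term so the LRT pair stays nested; a variance component estimated on the
zero boundary is a converged (singular) fit, not a failure, and does not
trigger this fallback. Post hoc machinery: Holm step-down adjustment
(statsmodels), Welch's t with Welch–Satterthwaite df (scipy), one-way ANOVA,
and OLS of log(P_crit) on log(weight-adjusted rate) with adjusted R²
(statsmodels).

## Synthetic data

The generators are deterministic functions of (config, seed) and define the
conditions under which the pipeline is validated.

**Genotypes.** Cluster centroids are per-locus dosage perturbations (replace
by a uniform draw from the other ploidy levels) of one base genotype; clones
perturb their centroid at a within-cluster rate. For two genotypes
independently perturbed from a common base at rates r₁, r₂ (ploidy 3), the
expected per-locus dissimilarity is (r₁ + r₂ − 2r₁r₂)·5/9 + r₁r₂·10/27;
this is inverted (least squares over per-cluster rates, within-rate
compensated) to hit the configured pairwise 1 − IBS targets. Defaults place
three clusters (5, 9, 9 clones — one historical, one mixed, one modern) at
pairwise dissimilarities of 0.10/0.11/0.11, inside the 8.75–11.49 % and
8.91–13.33 % bands observed for the study system, with 1 % within-cluster
divergence, 2 % missingness and negative-binomial depth (mean 30). The
emitted VCF carries internally consistent AO/SAF/SAR/RPR/RPL annotations and
can inject filter-failing sites on demand. The model is a dosage-level
caricature: no linkage, coalescent structure, or sequence-level error — so
passing tests demonstrate the correctness of the filtering/IBS/clustering
chain, not realism of the variation itself.

**Respirometry.** The well layout mirrors the experimental design: two
batches (default 11 and 12 clones, the reference clone in both) of 6 runs,
each run with one well per clone, 4 reference wells and 4 blanks, plus a
24-well sealed diffusion run. O₂ declines linearly at
(animal rate + diffusion + background) above P_crit and proportionally to O₂
below it (exponential decay, rate-continuous at the break); blanks decline at
background + diffusion, diffusion controls at diffusion only. Defaults: 6 h
at 2-min sampling from 100 % air saturation, animal rate 8 ± 3 %/h between
clones, diffusion 0.4, background 0.2, true P_crit 25, multiplicative
lognormal run effects (σ = 0.05) on animal rates. With these rates most
animals do not reach P_crit within 6 h, matching the design's observed
behaviour. A separate profile generator emits rate-vs-O₂ pairs (plateau
breaking to a conforming segment through the origin) for direct broken-stick
validation; with σ = 0 the pipeline inverts the generator exactly.

**T_imm.** Records follow grand mean + subpopulation effect + cluster effect
+ run effect + clone effect + residual, with clones split into the
study-shaped clusters (5 historical, 6+3 mixed, 9 modern), two batches of two
runs and 3 replicates per clone per run (6 per clone, ~138 rows). Defaults:
grand mean 600 s, subpopulation effect −120 s (modern lower), σ_run 30 s,
σ_clone 60 s, σ_residual 90 s, 5 % male and 10 % egg-bearing contamination to
exercise the exclusion rules. These magnitudes were chosen once as plausible
for an immobilization assay lasting minutes; the validated quantities
(type-I error, power, coverage) are properties of the design shape, not of
the particular second scale.

## Numerical choices and limitations

- Broken-stick ties between breakpoints resolve to the first (highest-O₂)
  minimizer; slope distinctness uses a 1e-8 relative tolerance.
- Variance ratios are floored at 1e-10 (reported as exactly 0), and the
  boundary is handled by the profile likelihood rather than a constrained
  solver.
- The IBS perturbation calibration errs by < ~0.005 absolute in expected
  dissimilarity (second-order perturbation collisions are modelled; chained
  centroid→clone reversions are not).
- `estimate_rate` is a single global OLS; it does not detect non-linearity
  from an animal crossing P_crit mid-trace. For P_crit work use the
  rolling-window profile.
- The binomial Laplace objective is known to be slightly biased for small
  cluster sizes (as is glmer at nAGQ = 1); no adaptive quadrature is
  implemented.
- Environmental models are deliberately not refitted: their underlying
  station/logger data are not available to the package.
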