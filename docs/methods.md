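# Methods

## The design in brief

The pipeline infers which phenotypes mediate the effect of an exposure
(alcohol consumption, drinks/week) on binary disease outcomes, in four
statistical stages: an agnostic phenome screen, two-sample Mendelian
randomisation (MR) of the screened phenotypes, a phenome-wide association
study (PheWAS) of the lead variant against ICD10-coded diseases, and
two-step MR mediation with the Sobel test. Each stage is an importable
module; the orchestrator chains them through plain-TSV intermediates.

## Phenome screen

For each phenotype `x` we fit the ordinary-least-squares model

    consumption ~ x + age + sex + deprivation + smoking + diabetes

on complete cases and report the Wald CI and two-sided p for the `x`
coefficient. Consumption is deliberately the *outcome* at this stage even
though MR later treats it as the exposure: the screen is a symmetric
association filter and this orientation keeps a single outcome vector across
thousands of models.

Significance is gated by a permutation empirical p-value
`P_e = (n+1)/(s+1)`, with `n` the number of permuted refits whose p-value is
*strictly* smaller than the observed one (ties count as not-smaller; the +1
smoothing keeps `P_e ≥ 1/(s+1)`) and `s` the number of permutations
(default 10,000; test suites use 200). Only the outcome vector is shuffled;
covariates stay attached to their rows, so the permutation tests the
composite null of no outcome association with the (predictor, covariate)
block. Permuted refits use the Frisch–Waugh–Lovell identity — residualise
the predictor and the permuted outcomes on the covariate block and read the
full-model t statistic off the residual regression. This is exact algebra
for the same OLS model, vectorises across permutations, and is
property-tested against statsmodels. `P_e` is invariant to any monotone
transform of the test statistic, so comparing |t| is equivalent to comparing
p-values.

Variance explained is `100·(R²_full − R²_reduced)` for the nested pair
fitted on identical rows; non-negative by construction. No multiplicity
adjustment is applied across phenotypes beyond the per-model permutation
gate — a deliberate looseness of the screen stage, since everything it
passes is re-tested causally downstream.

## Instrument selection

Instrument strength uses the t-statistic forms `R² = t²/(t² + n − 2)` and
`F = (n − 2)R²/(1 − R²)` (so `F = t²` for a single variant), which need only
the (beta, se, n) triple every summary-statistics dialect carries. The
allele-frequency form `2·eaf(1−eaf)β²` is provided as a cross-check utility;
the two agree for standardised traits. Instruments with `F < 10` are
removed as weak.

LD pruning is greedy: visit variants by ascending exposure p-value (ties:
larger F, then lexical id) and keep a variant iff its `r²` with every
already-kept variant is below the threshold (default 0.1; a pair at exactly
the threshold counts as "in LD" and is pruned). The kept set is maximal —
no pruned variant can be re-added. LD arrives as a matrix (e.g. computed
from a reference panel elsewhere); the package does not compute panel LD.

Harmonisation aligns exposure and outcome records to a shared effect
allele. The shared allele is canonicalised to the exposure *minor* allele
(lexically smaller allele on an exact 0.5 tie), which makes the output
exactly invariant under A1/A2 relabelling (with beta negation) of either
input — a stronger and more testable contract than orientation-preserving
harmonisers offer. Swapped outcome alleles flip the outcome beta and eaf;
a strand complement is applied when it resolves a non-palindromic mismatch.
Palindromic variants (A/T, C/G) cannot be oriented by labels: both allele
frequencies must fall outside `0.5 ± 0.08` (configurable) and agree on which
side the minor allele lies, otherwise the pair is dropped as
unharmonizable. Indels are rejected on read; only biallelic SNPs flow
through.

## Two-sample MR

The Wald ratio is `β_out/β_exp` with the first-order delta SE
`|se_out/β_exp|` (the second-order form adding
`β_out²·se_exp²/β_exp⁴` is available behind a flag). The multi-instrument
estimator is *fixed-effect* IVW — the inverse-variance weighted mean of the
per-variant ratios, algebraically the zero-intercept weighted regression of
outcome betas on exposure betas with weights `se_out⁻²`. Both formulations
are implemented (the regression route through statsmodels WLS) and must
agree to 1e-10; with one instrument IVW reduces exactly to the Wald ratio.

The pleiotropy test follows the simulation-based residual-sum-of-squares
idea: with `w_j = se_out,j⁻²` and `β₋j` the leave-one-out IVW slope,

    RSS_obs = Σ_j w_j (β_out,j − β₋j β_exp,j)²

is referred to a null distribution built by redrawing
`β_out,j ~ N(β₋j β_exp,j, se_out,j²)` `n_sim` times and recomputing the
statistic — including the leave-one-out slopes — on each draw; the global p
is `(#{RSS_sim ≥ RSS_obs}+1)/(n_sim+1)`. Each variant's observed residual
contribution is referred to its own simulated distribution and
Bonferroni-corrected across instruments; corrected p < 0.05 flags an
outlier (the threshold is a package choice). Flagged outliers are removed
and IVW re-estimated. The distortion test that some implementations add is
out of scope. `n_sim` defaults to 10,000 in release configs and 1,000 in
tests; at least 100 is enforced.

Calibration caveat: the resampling null treats the exposure betas as fixed
(the same no-measurement-error assumption the IVW weights make). With
realistic exposure-side noise the global p is mildly anticonservative; with
exact exposure betas it is uniform to KS precision. The test suite checks
uniformity in the exactly-calibrated regime and detection power in the
noisy regime.

Across phenotypes, multi- and single-instrument p-values are
Benjamini–Hochberg adjusted, and a phenotype is declared causal only when
the multi-instrument result passes `q < 0.05`, the single-instrument Wald
result passes `p < 0.05`, and the two betas agree in sign. P-values are
never displayed as zero (the formatter floors at "<1e-15").

## PheWAS

Disease groups are defined by ICD10 code prefixes via a user-supplied map
(group, prefix, role = case|exclude); a small built-in map mirrors the
classic alcohol-variant categories. An individual is a case on any code
matching a case prefix and a control only if free of all case and exclusion
prefixes; groups with fewer than 20 cases (standard PheWAS floor) are
skipped. Codes are normalised (dot stripped, upper-cased) and malformed
codes counted. The association model is maximum-likelihood logistic
regression of case status on additive dosage plus the screen covariates;
separation or non-convergence yields a flagged result with p = NaN rather
than an exception. The Bonferroni family size is the number of groups
actually tested, not attempted. A reference table of previously reported
UK-Biobank PheWAS rows for rs1229984 is bundled for internal-consistency
checks (exp(log-odds) versus the printed odds ratio); where the source
reports two slightly different p-values for the same row, the tabulated
value is carried.

## Mediation

Two-step MR: step 1 estimates exposure → mediator with the exposure's
instruments; step 2 estimates mediator → outcome with the mediator's
instruments, selected by the same strength/LD rules and passed through the
same outlier filter. The indirect effect is the product `a·b` with the
classic first-order Sobel SE `√(a²se_b² + b²se_a²)` and a two-sided normal
reference for `z = a·b/se` (the second-order variant adding `se_a²se_b²` is
behind a flag). The Sobel p is conservative relative to the exact
product-of-normals null for moderate z, which the suite verifies by Monte
Carlo. `a = b = 0` is returned as a degenerate result (indirect 0, p 1)
rather than an error. Direct effects and the proportion mediated are
deliberately not estimated. Results serialise to node/edge tables and a
Graphviz DOT rendering of the exposure–mediator–outcome network.

## Synthetic cohort generator

The generator is the package's study-conditions oracle, not a biobank
model. Defaults: 20,000 individuals; 60 biallelic SNPs with MAF uniform on
(0.1, 0.4) in LD blocks of two (latent-Gaussian correlation 0.6); 20 causal
variants, one per block, jointly explaining 10% of exposure variance with
random effect signs; exposure mean 8 drinks/week, SD 2, floored at zero
(the floor is kept rare deliberately, since the downstream estimators
assume an approximately linear genotype–exposure relation); a standard-
normal latent confounder entering exposure (coefficient 1) and mediator
(coefficient 0.3); mediator = GGT-like baseline 30 + `a`·(centred exposure)
+ confounder + small age trend + unit noise with `a = 0.5`; disease
Bernoulli with logit = −1.5 + `b`·(centred mediator) + direct·(centred
exposure) + pleiotropy, `b = 0.4`, so baseline prevalence ≈ 0.18 and the
true indirect effect is 0.2. One variant carries a direct log-odds effect
(0.12/allele by default) — planted on a *causal* variant, because only an
exposure-associated variant can enter the instrument set and bias MR, which
is exactly the scenario the outlier test exists for. Exclusion flags
(non-drinker, special-occasion-only, changed-habits, cancer, CVD, pregnancy,
missing sex, missing exposure) are assigned at ~2% each and applied in a
fixed cascade, tallying each individual at the first criterion met, so the
tally plus the survivors partition the input.

Genotypes come from a latent multivariate normal thresholded twice per
individual (once per haplotype), giving Hardy–Weinberg-consistent dosages
with tunable block `r²` and no haplotype machinery. Thresholding attenuates
the latent correlation (0.9 latent ≈ 0.6–0.65 dosage r²), which the tests
account for. Two-sample structure is a disjoint random split of the cohort:
the exposure (or step-2 mediator) GWAS runs in one half and the outcome GWAS
in the other, so no individual contributes to both tables. Per-variant
linear GWAS is vectorised closed-form OLS; binary outcomes use per-variant
logistic fits.

What the generator does *not* emulate: population stratification beyond the
single confounder, haplotype/coalescent LD, imputation uncertainty,
genotype missingness, case ascertainment, or real phenome correlation
structure. Passing tests therefore demonstrate correctness and calibration
of the estimators under the stated generative assumptions, not performance
on real biobank data.

## Calibration studies and problem sizes

`mrpath.calibration` packages the repeated-draw studies the test suite and
the acceptance script share. Estimator-level studies (IVW CI coverage at a
true effect of 0.3, 20 instruments, n = 20,000 per sample, 300 seeds;
pleiotropy-outlier detection with a planted direct effect 5× the mediated
one, 100 seeds at n_sim = 1,000; Sobel CI coverage, 500 seeds) draw summary
statistics directly from their sampling distributions — the standard
construction for MR calibration work. The end-to-end study
(50 seeds) runs the full individual-level chain: simulate, exclude, split,
GWAS both halves, select instruments on empirical dosage LD, both MR steps
with outlier correction, Sobel. These sizes keep the whole suite under a
minute of simulation time while leaving the binomial noise of each rate
well inside its acceptance band.

## Numerical and design choices

- Seeds are mandatory everywhere; generators use numpy `default_rng` with
  stable per-purpose substreams, and the pipeline fans one global seed out
  to per-stage seeds by hashing the stage name, so toggling a stage off
  never perturbs another stage's stream. Identical seeds give bit-identical
  outputs.
- All intermediates are TSV with a '#'-prefixed metadata header (pipeline
  version, seed, config hash); one canonical summary-statistics dialect
  (SNP CHR BP A1 A2 EAF BETA SE P N, 1-based positions, '.' for missing)
  with a column-mapping shim for foreign dialects. Records violating the
  field invariants are dropped with logged reasons, not errors; a p-value
  inconsistent with |beta/se| by more than two orders of magnitude warns
  only, since published statistics often carry rounded p.
- Rank-deficient screen designs raise an error naming the collinear
  columns; LD matrices are symmetrised when asymmetry ≤ 1e-6 and rejected
  beyond; dosage files follow the plink `.raw` additive convention
  (FID, IID, then `id_A1` columns).
- Known limitations: fixed-effect (not random-effect) IVW; no MR-Egger,
  weighted-median or mode estimators; no beverage-specific instruments; no
  multivariable-MR mediation; the screen's permutation gate is the only
  multiplicity control at stage 1.
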