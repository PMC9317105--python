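# mrpath

Multi-stage causal inference linking an exposure (alcohol consumption) to
molecular and lifestyle mediators and to disease outcomes, implemented as a
reusable, fully tested Python pipeline:

1. **Phenome screen** — covariate-adjusted linear models of beverage
   consumption on each of many phenotypes, gated by a permutation empirical
   p-value `P_e = (n + 1) / (s + 1)`, where `n` counts permuted refits whose
   p-value beats the observed one out of `s` permutations, with the
   percentage of consumption variance each phenotype explains.
2. **Instrument selection** — per-variant variance explained
   `R² = t² / (t² + n − 2)` and `F = (n − 2) R² / (1 − R²)`; weak instruments
   (`F < 10`) removed; greedy LD pruning at `r² < 0.1`; harmonisation of
   exposure and outcome summary statistics to a shared effect allele with
   palindromic-variant resolution by allele frequency.
3. **Two-sample Mendelian randomisation** — the Wald ratio
   `β_out / β_exp` for single instruments; fixed-effect inverse-variance
   weighting `β_IVW = Σ w_j r_j / Σ w_j` with `r_j = β_out,j / β_exp,j` and
   `w_j = β_exp,j² / se_out,j²`; a simulation-based residual-sum-of-squares
   test that flags and removes horizontally pleiotropic outlier instruments;
   Benjamini–Hochberg FDR across phenotypes; and a consistency filter
   requiring agreement in sign and significance between single- and
   multi-instrument analyses.
4. **PheWAS** — adjusted logistic regression of one variant's additive dosage
   against many binary ICD10-coded disease groups, Bonferroni-corrected.
5. **Mediation** — two-step MR (exposure → mediator, mediator → outcome)
   combined by the Sobel test: indirect effect `a·b` with
   `se = √(a² se_b² + b² se_a²)`.

Because the individual-level biobank data behind this design are not
redistributable, the package ships a first-class **synthetic-cohort
generator** with planted causal, confounding, pleiotropic and LD structure
(and the matching exclusion cascade), so every stage is verifiable against
known ground truth at desk scale.

## Who this is for

Genetic epidemiologists and biostatisticians who want a transparent,
end-to-end reference implementation of this screen → MR → PheWAS → mediation
design that can be exercised, calibrated and extended without restricted
data access.

## Worked example

`examples/05_mediation.py` runs the full mediation chain on a synthetic
cohort of 20,000 individuals in which alcohol consumption raises a GGT-like
biomarker (`a = 0.5` biomarker units per drink/week) and the biomarker
raises disease risk (`b = 0.4` log-odds per unit), so the true indirect
effect is `a·b = 0.2`:

```
step 1 (exposure -> mediator):  a = 0.471 (se 0.025), 21 instruments
step 2 (mediator -> disease):   b = 0.351 (se 0.076), 18 instruments
indirect effect a*b = 0.165 (Sobel se 0.037, 95% CI 0.093, 0.238, p = 8.1e-06)
planted truth: 0.2
```

Step 1 estimates the causal effect of consumption on the biomarker from
disjoint GWAS samples; step 2 does the same for biomarker → disease with the
pleiotropy-outlier filter applied; the Sobel CI covers the planted 0.2.
Similarly, `examples/03_mendelian_randomisation.py` plants one pleiotropic
instrument among twenty and shows the outlier test catching it:

```
IVW with pleiotropic instrument: beta = 0.353 (95% CI 0.309, 0.398)
global RSS p = 9.999e-05; flagged outliers: ['rs000020']
outlier-corrected IVW:           beta = 0.275 (95% CI 0.229, 0.321)
```

The other examples cover the screen (`01`), instrument selection (`02`),
PheWAS (`04`) and the one-command demo pipeline (`06`, also available as
`mrpath demo`), which writes every intermediate as TSV plus a run manifest,
a Manhattan-style screen plot and a mediation network DOT file.

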