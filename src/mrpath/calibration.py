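"""Repeated-draw calibration studies for the pipeline's estimators.

These functions run the package's own estimators over many seeded replicates
and report coverage / detection / recovery rates.  Estimator-level studies
(IVW coverage, pleiotropy-outlier detection, Sobel coverage) draw GWAS
estimates from their sampling distributions at a stated per-sample n — the
standard construction for MR method calibration; the mediation-recovery study
runs the full individual-level generator end to end (genotypes, cohort,
exclusions, disjoint two-sample GWAS, instrument selection, both MR steps,
Sobel).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import mediation, mr, simulate
from .instruments import instrument_strength, ld_prune, harmonize

__all__ = [
    "ivw_coverage",
    "pleiotropy_detection",
    "sobel_coverage",
    "ivw_formulation_agreement",
    "mediation_recovery",
    "recover_indirect",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 for portability of the seed contract
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def ivw_coverage(
    n_seeds: int = 300,
    n_instruments: int = 20,
    n_per_sample: int = 20_000,
    causal_effect: float = 0.3,
    seed: int = 0,
) -> float:
    """Fraction of replicates whose IVW 95% CI covers the true causal effect."""
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        pairs, truth = simulate.simulate_summary_instruments(
            n_instruments=n_instruments, n_per_sample=n_per_sample,
            causal_effect=causal_effect, seed=s,
        )
        res = mr.ivw(pairs)
        hits += res.ci_low <= truth["causal_effect"] <= res.ci_high
    return hits / n_seeds


def pleiotropy_detection(
    n_seeds: int = 100,
    n_instruments: int = 20,
    n_per_sample: int = 20_000,
    causal_effect: float = 0.3,
    pleiotropy_ratio: float = 5.0,
    n_sim: int = 1_000,
    seed: int = 0,
) -> dict[str, float]:
    """Detection and bias-reduction rates for one planted pleiotropic instrument.

    The planted variant's direct outcome effect is ``pleiotropy_ratio`` times
    its mediated effect (causal_effect * its exposure beta).  Returns the
    fraction of replicates in which the variant is flagged, and — among the
    flagged ones — the fraction in which the outlier-corrected IVW lands
    closer to the truth than the uncorrected IVW.
    """
    flagged = 0
    improved = 0
    for s in _child_seeds(seed, n_seeds):
        pairs, truth = simulate.simulate_summary_instruments(
            n_instruments=n_instruments, n_per_sample=n_per_sample,
            causal_effect=causal_effect, pleiotropy_ratio=pleiotropy_ratio,
            seed=s,
        )
        report = mr.pleiotropy_test(pairs, n_sim=n_sim, seed=s)
        target = truth["pleiotropic_snps"][0]
        if target in report.outliers:
            flagged += 1
            plain = mr.ivw(pairs)
            corrected = mr.outlier_corrected_ivw(pairs, report)
            if abs(corrected.beta - causal_effect) < abs(plain.beta - causal_effect):
                improved += 1
    return {
        "detection_rate": flagged / n_seeds,
        "improvement_rate": improved / flagged if flagged else 0.0,
        "n_flagged": flagged,
    }


def sobel_coverage(
    n_seeds: int = 500,
    a: float = 0.5,
    se_a: float = 0.03,
    b: float = 0.4,
    se_b: float = 0.05,
    seed: int = 0,
) -> float:
    """Coverage of the Sobel 95% CI for a planted indirect effect a*b.

    Estimates of a and b are drawn from their (large-n normal) sampling
    distributions; each replicate's CI is checked against the true product.
    """
    rng = np.random.default_rng(seed)
    truth = a * b
    hits = 0
    for _ in range(n_seeds):
        ahat = rng.normal(a, se_a)
        bhat = rng.normal(b, se_b)
        res = mediation.sobel(ahat, se_a, bhat, se_b)
        hits += res.ci_low <= truth <= res.ci_high
    return hits / n_seeds


def ivw_formulation_agreement(n_fixtures: int = 1_000, seed: int = 0) -> float:
    """Max |difference| between the weighted-mean and WLS-regression IVW betas."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        m = int(rng.integers(2, 21))
        pairs = pd.DataFrame({
            "SNP": [f"v{i}" for i in range(m)],
            "beta_exp": rng.normal(0.2, 0.1, m) + 0.05 * rng.choice([-1, 1], m),
            "se_exp": rng.uniform(0.01, 0.05, m),
            "beta_out": rng.normal(0.0, 0.2, m),
            "se_out": rng.uniform(0.01, 0.1, m),
        })
        pairs = pairs[pairs["beta_exp"].abs() > 1e-3]
        if len(pairs) < 2:
            continue
        d = abs(mr.ivw(pairs).beta - mr.ivw_regression(pairs).beta)
        worst = max(worst, d)
    return worst


def recover_indirect(
    seed: int,
    config: simulate.SimulationConfig | None = None,
    split_fraction: float = 0.5,
    f_min: float = 10.0,
    r2_max: float = 0.1,
    n_sim: int = 1_000,
) -> mediation.MediationResult:
    """One end-to-end mediation recovery run on the individual-level generator.

    Simulates a cohort under ``config`` (reseeded with ``seed``), applies the
    exclusion cascade, splits into two disjoint GWAS samples, selects
    instruments (weak-instrument filter at ``f_min``, LD pruning on the
    empirical dosage r^2 at ``r2_max``), estimates step 1
    (exposure -> mediator, IVW) and step 2 (mediator -> disease,
    outlier-corrected IVW), and combines them with the Sobel test.
    """
    cfg = (config or simulate.SimulationConfig()).with_seed(seed)
    geno = simulate.simulate_genotypes(cfg)
    cohort, truth = simulate.simulate_cohort(cfg, geno)
    cohort, _ = simulate.apply_exclusions(cohort)
    ids_a, ids_b = simulate.split_cohort(cohort, split_fraction, cfg.seed)
    geno_a, geno_b = geno.subset(ids_a), geno.subset(ids_b)
    ld = geno_a.empirical_ld()

    def select(sumstats):
        stats = instrument_strength(sumstats, f_min=f_min)
        strong = stats[stats["kept"]].copy()
        pruned = ld_prune(strong, ld, threshold=r2_max)
        return sumstats[sumstats["SNP"].isin(pruned.loc[pruned["kept"], "SNP"])]

    # step 1: exposure (sample A) -> mediator (sample B)
    exp_a = simulate.gwas_linear(cohort.loc[ids_a, "exposure"].to_numpy(), geno_a)
    med_b = simulate.gwas_linear(cohort.loc[ids_b, "mediator"].to_numpy(), geno_b)
    pairs1, _ = harmonize(select(exp_a), med_b)
    step1 = mr.ivw(pairs1)

    # step 2: mediator (sample A) -> disease (sample B)
    med_a = simulate.gwas_linear(cohort.loc[ids_a, "mediator"].to_numpy(), geno_a)
    dis_b = simulate.gwas_logistic(cohort.loc[ids_b, "disease"].to_numpy(), geno_b)
    dis_b = dis_b.dropna(subset=["BETA", "SE"])
    pairs2, _ = harmonize(select(med_a), dis_b)
    if len(pairs2) >= 4:
        report = mr.pleiotropy_test(pairs2, n_sim=n_sim, seed=seed)
        try:
            step2 = mr.outlier_corrected_ivw(pairs2, report)
        except Exception:
            step2 = mr.ivw(pairs2)
    else:
        step2 = mr.ivw(pairs2)

    result = mediation.two_step_mediation(
        step1, step2, labels=("alcohol_consumption", "mediator", "disease")
    )
    result.true_indirect = truth.indirect  # attached for recovery studies
    return result


def mediation_recovery(
    n_seeds: int = 50,
    config: simulate.SimulationConfig | None = None,
    se_multiple: float = 3.0,
    seed: int = 0,
) -> float:
    """Fraction of end-to-end runs recovering the planted indirect effect.

    A run counts as recovered when the estimated indirect effect lies within
    ``se_multiple`` Sobel standard errors of the planted a*b.
    """
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        res = recover_indirect(s, config=config)
        hits += abs(res.indirect - res.true_indirect) <= se_multiple * res.se_indirect
    return hits / n_seeds
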