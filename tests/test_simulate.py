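"""Generator properties: determinism, Hardy-Weinberg, LD structure, planted
effect recovery, exclusion-cascade partitioning and two-sample splitting."""

import numpy as np
import pandas as pd
import pytest

from mrpath import (
    AnalysisError,
    ConfigError,
    SimulationConfig,
    apply_exclusions,
    make_two_sample_sumstats,
    simulate_cohort,
    simulate_genotypes,
    split_cohort,
)
from mrpath.simulate import EXCLUSION_ORDER, gwas_linear


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(maf_range=(0.0, 0.3), seed=1)
    with pytest.raises(ConfigError):
        SimulationConfig(maf_range=(0.1, 0.6), seed=1)
    with pytest.raises(ConfigError):
        SimulationConfig(n_variants=10, n_causal=8, n_pleiotropic=3, seed=1)
    with pytest.raises(ConfigError):
        SimulationConfig(exposure_variance_explained=1.0, seed=1)


def test_determinism_under_seed(small_config):
    g1 = simulate_genotypes(small_config)
    g2 = simulate_genotypes(small_config)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    c1, t1 = simulate_cohort(small_config, g1)
    c2, _ = simulate_cohort(small_config, g2)
    pd.testing.assert_frame_equal(c1, c2)
    g3 = simulate_genotypes(small_config.with_seed(99))
    assert not np.array_equal(g1.dosages, g3.dosages)


def test_hardy_weinberg_at_half():
    cfg = SimulationConfig(n_individuals=20_000, n_variants=8,
                           maf_range=(0.5, 0.5), ld_block_size=1,
                           ld_within_block_r=0.0, n_causal=4, seed=3)
    g = simulate_genotypes(cfg)
    for j in range(g.n_variants):
        freqs = np.bincount(g.dosages[:, j].astype(int), minlength=3) / cfg.n_individuals
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)


def test_independent_variants_uncorrelated():
    cfg = SimulationConfig(n_individuals=2_000, n_variants=1_000,
                           maf_range=(0.3, 0.3), ld_block_size=1,
                           ld_within_block_r=0.0, n_causal=10, seed=4)
    g = simulate_genotypes(cfg)
    r = np.corrcoef(g.dosages, rowvar=False)
    off = r[np.triu_indices_from(r, k=1)]
    assert np.mean(np.abs(off)) < 0.05


def test_block_ld_exceeds_prune_threshold():
    # latent r = 0.9 in blocks of two: dosage r2 well above the 0.1 threshold
    cfg = SimulationConfig(n_individuals=10_000, n_variants=60,
                           ld_block_size=2, ld_within_block_r=0.9,
                           n_causal=20, seed=5)
    g = simulate_genotypes(cfg)
    ld = g.empirical_ld().to_numpy()
    within = [ld[i, i + 1] for i in range(0, 60, 2)]
    assert np.mean(np.asarray(within) > 0.1) >= 0.90


def test_exposure_variance_share_recovered():
    """Regression of exposure on the true genetic score gives R2 near the target."""
    r2s = []
    for seed in range(10):
        cfg = SimulationConfig(seed=100 + seed)
        g = simulate_genotypes(cfg)
        cohort, truth = simulate_cohort(cfg, g)
        score = (g.dosages - 2 * g.variants["MAF"].to_numpy()) @ truth.beta_exposure
        keep = cohort["exposure"].notna().to_numpy()
        r = np.corrcoef(score[keep], cohort["exposure"].to_numpy()[keep])[0, 1]
        r2s.append(r * r)
    assert abs(np.mean(r2s) - 0.10) < 0.02


def test_null_model_breaks_exposure_disease_link():
    cfg = SimulationConfig(path_a=0.0, direct_effect=0.0, n_pleiotropic=0,
                           pleiotropy_effect=0.0, n_individuals=20_000, seed=6)
    g = simulate_genotypes(cfg)
    cohort, truth = simulate_cohort(cfg, g)
    assert truth.indirect == 0.0
    keep = cohort["exposure"].notna()
    r = np.corrcoef(cohort.loc[keep, "exposure"], cohort.loc[keep, "disease"])[0, 1]
    assert abs(r) < 0.03


def _flagged_cohort():
    """100 rows; 10 non-drinkers, 5 of whom also have cancer; 3 extra cancer."""
    n = 100
    cohort = pd.DataFrame({
        "iid": np.arange(n),
        "exposure": np.full(n, 5.0),
        **{c: np.zeros(n, dtype=int) for c in EXCLUSION_ORDER[:-1]},
    })
    cohort.loc[0:9, "non_drinker"] = 1
    cohort.loc[5:12, "cancer"] = 1  # rows 5..9 overlap the non-drinkers
    return cohort


def test_exclusion_tally_counts_first_criterion_only():
    cohort = _flagged_cohort()
    filtered, tally = apply_exclusions(cohort)
    # brute-force set arithmetic oracle
    non_drinkers = set(range(10))
    cancer = set(range(5, 13))
    assert tally["non_drinker"] == len(non_drinkers) == 10
    assert tally["cancer"] == len(cancer - non_drinkers) == 3
    assert len(filtered) == 100 - len(non_drinkers | cancer)
    assert sum(tally.values()) + len(filtered) == 100


def test_exclusions_identity_and_total(small_cohort):
    _, cohort, _ = small_cohort
    clean = cohort.copy()
    for c in EXCLUSION_ORDER[:-1]:
        clean[c] = 0
    clean["exposure"] = clean["exposure"].fillna(1.0)
    out, tally = apply_exclusions(clean)
    assert all(v == 0 for v in tally.values())
    pd.testing.assert_frame_equal(out, clean)

    allflag = cohort.copy()
    allflag["cancer"] = 1
    out, tally = apply_exclusions(allflag)
    assert len(out) == 0
    assert sum(tally.values()) == len(cohort)


def test_exclusion_partition_invariant(small_cohort):
    _, cohort, _ = small_cohort
    filtered, tally = apply_exclusions(cohort)
    assert sum(tally.values()) + len(filtered) == len(cohort)


def test_split_is_deterministic_disjoint_and_guarded(small_cohort):
    _, cohort, _ = small_cohort
    a1, b1 = split_cohort(cohort, 0.5, seed=1)
    a2, b2 = split_cohort(cohort, 0.5, seed=1)
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_array_equal(b1, b2)
    assert len(set(a1) & set(b1)) == 0
    assert len(a1) + len(b1) == len(cohort)
    with pytest.raises(AnalysisError):
        split_cohort(cohort.head(60), 0.5, seed=1)


def test_two_sample_gwas_calibration_and_recovery():
    cfg = SimulationConfig(n_individuals=8_000, n_variants=400, n_causal=20,
                           ld_block_size=1, ld_within_block_r=0.0,
                           exclusion_fraction=0.0, seed=8)
    g = simulate_genotypes(cfg)
    cohort, truth = simulate_cohort(cfg, g)
    exp_stats, _ = make_two_sample_sumstats(cohort, g, outcome="mediator", seed=8)

    null_idx = np.setdiff1d(np.arange(cfg.n_variants), truth.causal_idx)
    z_null = (exp_stats["BETA"] / exp_stats["SE"]).to_numpy()[null_idx]
    assert np.mean(np.abs(z_null) < 3.0) >= 0.99  # type-I calibration

    bhat = exp_stats["BETA"].to_numpy()[truth.causal_idx]
    se = exp_stats["SE"].to_numpy()[truth.causal_idx]
    bstar = truth.beta_exposure[truth.causal_idx]
    assert np.mean(np.abs(bhat - bstar) < 3 * se) >= 0.90


def test_outcome_beta_proportional_to_exposure_beta():
    """Mediator GWAS betas across instruments scale as path_a times exposure betas."""
    cfg = SimulationConfig(exclusion_fraction=0.0, seed=9)
    g = simulate_genotypes(cfg)
    cohort, truth = simulate_cohort(cfg, g)
    med = gwas_linear(cohort["mediator"].to_numpy(), g)
    idx = truth.causal_idx
    bx = truth.beta_exposure[idx]
    by = med["BETA"].to_numpy()[idx]
    slope = np.sum(bx * by) / np.sum(bx * bx)  # through-origin regression
    assert abs(slope - truth.path_a) / truth.path_a < 0.10


def test_gwas_refuses_missing_exposure(small_cohort):
    g, cohort, _ = small_cohort
    with pytest.raises(AnalysisError):
        make_two_sample_sumstats(cohort, g, seed=1)
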