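import numpy as np
import pandas as pd
import pytest

from mrpath import SimulationConfig, simulate_cohort, simulate_genotypes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale cohort used by several stages: fast but non-trivial."""
    return SimulationConfig(n_individuals=4_000, n_variants=40, n_causal=12,
                            seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    geno = simulate_genotypes(small_config)
    cohort, truth = simulate_cohort(small_config, geno)
    return geno, cohort, truth


def random_sumstats(rng: np.random.Generator, n_variants: int = 12,
                    palindromic: bool = False) -> pd.DataFrame:
    """Random valid GWAS summary table for round-trip and harmonisation tests."""
    pairs = [("A", "T"), ("C", "G")] if palindromic else [
        ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), n_variants)]
    beta = rng.normal(0.0, 0.3, n_variants)
    se = rng.uniform(0.01, 0.2, n_variants)
    from scipy.stats import norm
    p = np.clip(2 * norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    return pd.DataFrame({
        "SNP": [f"rs{i:05d}" for i in range(n_variants)],
        "CHR": "1",
        "BP": np.arange(1, n_variants + 1) * 1000,
        "A1": [a for a, _ in alleles],
        "A2": [b for _, b in alleles],
        "EAF": rng.uniform(0.05, 0.45, n_variants),
        "BETA": beta,
        "SE": se,
        "P": p,
        "N": rng.integers(5_000, 50_000, n_variants),
    })
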