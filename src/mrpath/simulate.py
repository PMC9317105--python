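"""Synthetic cohort, genotype and two-sample GWAS generator with planted causal structure.

The generator emulates the data-generating assumptions behind an
alcohol-consumption study design: additive SNP effects on a continuous
exposure (drinks/week), a continuous biomarker mediator (GGT-like, U/L scale)
on the exposure -> binary-disease path, a shared latent confounder of exposure
and mediator, optional horizontally pleiotropic variants with a direct
log-odds effect on the disease, block linkage disequilibrium, and a
Figure-1-style exclusion cascade.  Ground truth is returned alongside the
data so every downstream estimator can be checked for parameter recovery.

Genotypes are drawn blockwise from a latent Gaussian that is thresholded twice
per individual (one threshold pass per haplotype), which yields
Hardy-Weinberg-consistent dosages with tunable within-block correlation and
no haplotype machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .errors import AnalysisError, ConfigError

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "TrueEffects",
    "simulate_genotypes",
    "simulate_cohort",
    "apply_exclusions",
    "split_cohort",
    "gwas_linear",
    "gwas_logistic",
    "make_two_sample_sumstats",
    "simulate_summary_instruments",
    "EXCLUSION_ORDER",
]

_BASES = np.array(list("ACGT"))

#: Order in which the exclusion cascade is applied; each individual is tallied
#: at the first criterion met (withdrawn consent is folded into missing_sex,
#: the record-level "cannot analyse" flag).
EXCLUSION_ORDER = (
    "missing_sex",
    "non_drinker",
    "special_occasion_only",
    "changed_habits",
    "cancer",
    "cvd",
    "pregnant",
    "missing_exposure",
)

_FLAG_COLUMNS = EXCLUSION_ORDER[:-1]  # missing_exposure is data-derived, not a flag


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the synthetic study.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 20,000 individuals, 60 variants in LD blocks of two, 20 causal
    variants jointly explaining 10% of exposure variance, mediation paths
    a=0.5 (mediator units per drink/week) and b=0.4 (log-odds per mediator
    unit), and one pleiotropic instrument.
    """

    n_individuals: int = 20_000
    n_variants: int = 60
    maf_range: tuple[float, float] = (0.1, 0.4)
    exposure_variance_explained: float = 0.10
    n_causal: int = 20
    n_pleiotropic: int = 1
    pleiotropy_effect: float = 0.12
    path_a: float = 0.5
    path_b: float = 0.4
    direct_effect: float = 0.0
    confounder_effect: float = 0.3
    outcome_baseline_logodds: float = -1.5
    exposure_mean: float = 8.0
    exposure_sd: float = 2.0
    mediator_baseline: float = 30.0
    ld_block_size: int = 2
    ld_within_block_r: float = 0.6
    exclusion_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.exposure_variance_explained < 1.0):
            raise ConfigError("exposure_variance_explained must be in [0, 1)")
        if self.n_causal + self.n_pleiotropic > self.n_variants:
            raise ConfigError("n_causal + n_pleiotropic must not exceed n_variants")
        if self.n_causal < 0 or self.n_pleiotropic < 0:
            raise ConfigError("variant counts must be non-negative")
        if not (0.0 <= self.ld_within_block_r < 1.0):
            raise ConfigError("ld_within_block_r must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ConfigError("n_individuals and n_variants must be positive")
        if not (0.0 <= self.exclusion_fraction < 1.0):
            raise ConfigError("exclusion_fraction must be in [0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed is mandatory and must be an integer")
        resid = self.exposure_sd**2 * (1.0 - self.exposure_variance_explained) - 1.0
        if resid <= 0:
            raise ConfigError(
                "exposure_sd too small: residual variance after the genetic and "
                "confounder components would be non-positive"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of config keys")
        if "seed" not in raw:
            raise ConfigError(f"{path}: seed is mandatory")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosages plus variant metadata."""

    dosages: np.ndarray  # (n, m) float64 with values in {0, 1, 2}
    variants: pd.DataFrame  # columns SNP, CHR, BP, A1, A2, MAF
    iids: np.ndarray  # individual ids aligned with dosage rows

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset(self, iids) -> "GenotypeMatrix":
        """Rows restricted to ``iids`` (order preserved from the argument)."""
        pos = pd.Index(self.iids).get_indexer(iids)
        if (pos < 0).any():
            raise AnalysisError("requested individuals absent from genotype matrix")
        return GenotypeMatrix(self.dosages[pos], self.variants, np.asarray(iids))

    def empirical_ld(self) -> pd.DataFrame:
        """Pairwise dosage r-squared, unit diagonal, indexed by variant id."""
        r = np.corrcoef(self.dosages, rowvar=False)
        r2 = np.clip(r * r, 0.0, 1.0)
        np.fill_diagonal(r2, 1.0)
        ids = self.variants["SNP"].to_numpy()
        return pd.DataFrame(r2, index=ids, columns=ids)


@dataclass
class TrueEffects:
    """Ground truth planted by :func:`simulate_cohort`."""

    beta_exposure: np.ndarray  # per-allele effect on exposure (drinks/week)
    beta_outcome_direct: np.ndarray  # per-allele pleiotropic log-odds effect
    causal_idx: np.ndarray
    pleiotropic_idx: np.ndarray
    path_a: float
    path_b: float
    direct_effect: float

    @property
    def indirect(self) -> float:
        """True mediated (indirect) effect a*b on the log-odds scale."""
        return self.path_a * self.path_b

    @property
    def causal_effect_disease(self) -> float:
        """Total exposure->disease log-odds effect per drink/week."""
        return self.path_a * self.path_b + self.direct_effect

    @property
    def causal_effect_mediator(self) -> float:
        return self.path_a


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Stable per-purpose substreams so that e.g. regenerating flags does not
    # perturb the genotype draw.
    return np.random.default_rng([int(config.seed), stream])


def _block_slices(n_variants: int, block: int):
    return [slice(i, min(i + block, n_variants)) for i in range(0, n_variants, block)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw additive dosages in LD blocks via latent-Gaussian thresholding.

    Each individual gets two independent latent multivariate-normal draws per
    block (off-diagonal correlation ``ld_within_block_r``); each draw is
    thresholded at the variant's allele-frequency quantile and the two allele
    indicators are summed, so marginal dosages are Hardy-Weinberg consistent.
    """
    rng = _rng(config, 0)
    n, m = config.n_individuals, config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    thresholds = norm.ppf(mafs)

    dosages = np.empty((n, m), dtype=np.float64)
    r = config.ld_within_block_r
    for sl in _block_slices(m, config.ld_block_size):
        k = sl.stop - sl.start
        if k == 1 or r == 0.0:
            latent = rng.standard_normal((2, n, k))
        else:
            cov = np.full((k, k), r)
            np.fill_diagonal(cov, 1.0)
            chol = np.linalg.cholesky(cov)
            latent = rng.standard_normal((2, n, k)) @ chol.T
        alleles = latent < thresholds[sl]
        dosages[:, sl] = alleles.sum(axis=0)

    allele_idx = rng.integers(0, 4, size=(m, 2))
    # re-draw ties so A1 != A2
    while (tie := allele_idx[:, 0] == allele_idx[:, 1]).any():
        allele_idx[tie, 1] = rng.integers(0, 4, size=int(tie.sum()))
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1:06d}" for i in range(m)],
            "CHR": np.repeat(1, m),
            "BP": np.arange(1, m + 1) * 10_000,
            "A1": _BASES[allele_idx[:, 0]],
            "A2": _BASES[allele_idx[:, 1]],
            "MAF": mafs,
        }
    )
    iids = np.arange(1, n + 1)
    return GenotypeMatrix(dosages, variants, iids)


def _planted_effects(config: SimulationConfig, mafs: np.ndarray) -> TrueEffects:
    """Assign per-variant exposure betas and pleiotropic outcome betas.

    Causal variants are placed one per LD block (independent loci) so that LD
    pruning does not thin the instrument set; each contributes an equal share
    of ``exposure_variance_explained``.  Pleiotropic direct-outcome effects go
    on the tail of the causal list so they are real instruments and can bias
    the MR estimate, which is the scenario the outlier test must detect.
    """
    m = len(mafs)
    rng = _rng(config, 1)
    block_starts = [sl.start for sl in _block_slices(m, config.ld_block_size)]
    order = block_starts + [i for i in range(m) if i not in set(block_starts)]
    causal = np.array(sorted(order[: config.n_causal]), dtype=int)

    beta_exposure = np.zeros(m)
    if config.n_causal:
        share = config.exposure_variance_explained / config.n_causal
        var_g = 2.0 * mafs[causal] * (1.0 - mafs[causal])
        signs = rng.choice([-1.0, 1.0], size=config.n_causal)
        beta_exposure[causal] = signs * config.exposure_sd * np.sqrt(share / var_g)

    pleio = causal[config.n_causal - config.n_pleiotropic :] if config.n_pleiotropic else np.array([], dtype=int)
    beta_direct = np.zeros(m)
    beta_direct[pleio] = config.pleiotropy_effect
    return TrueEffects(
        beta_exposure=beta_exposure,
        beta_outcome_direct=beta_direct,
        causal_idx=causal,
        pleiotropic_idx=pleio,
        path_a=config.path_a,
        path_b=config.path_b,
        direct_effect=config.direct_effect,
    )


def simulate_cohort(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> tuple[pd.DataFrame, TrueEffects]:
    """Generate the per-individual cohort table and its ground truth.

    exposure  = mean + genetic score + confounder + sex shift + noise, floored at 0
    mediator  = baseline + a*(exposure - mean) + c*confounder + age trend + noise
    disease   ~ Bernoulli(logistic(b0 + b*(mediator - baseline)
                                   + direct*(exposure - mean) + pleiotropy))

    The genetic score is scaled so its variance share of the (pre-truncation)
    exposure equals ``exposure_variance_explained``.
    """
    if genotypes.n_individuals != config.n_individuals:
        raise ConfigError("genotype row count must equal n_individuals")
    rng = _rng(config, 2)
    n = config.n_individuals
    mafs = genotypes.variants["MAF"].to_numpy()
    truth = _planted_effects(config, mafs)

    g_centered = genotypes.dosages - 2.0 * mafs
    gscore = g_centered @ truth.beta_exposure
    confounder = rng.standard_normal(n)

    age = rng.normal(55.5, 8.0, n)
    sex = rng.binomial(1, 0.48, n)  # 1 = male
    deprivation = rng.normal(0.0, 3.0, n)
    smoking = rng.choice([0, 1, 2], size=n, p=[0.54, 0.35, 0.11])
    diabetes = rng.binomial(1, 0.026, n)

    resid_sd = np.sqrt(config.exposure_sd**2 * (1 - config.exposure_variance_explained) - 1.0)
    exposure = (
        config.exposure_mean
        + gscore
        + confounder
        + 0.8 * (sex - 0.48)
        + rng.normal(0.0, resid_sd, n)
    )
    exposure = np.maximum(exposure, 0.0)

    mediator = (
        config.mediator_baseline
        + config.path_a * (exposure - config.exposure_mean)
        + config.confounder_effect * confounder
        + 0.05 * (age - 55.5)
        + rng.standard_normal(n)
    )

    linpred = (
        config.outcome_baseline_logodds
        + config.path_b * (mediator - config.mediator_baseline)
        + config.direct_effect * (exposure - config.exposure_mean)
        + g_centered @ truth.beta_outcome_direct
    )
    disease = rng.binomial(1, expit(linpred))

    frng = _rng(config, 3)
    f = config.exclusion_fraction
    flags = {
        "non_drinker": frng.random(n) < f,
        "special_occasion_only": frng.random(n) < f,
        "changed_habits": frng.random(n) < f,
        "cancer": frng.random(n) < f,
        "cvd": frng.random(n) < f,
        "pregnant": (frng.random(n) < f) & (sex == 0),
        "missing_sex": frng.random(n) < f / 10.0,
    }
    missing_exposure = frng.random(n) < f / 5.0
    exposure = exposure.copy()
    exposure[missing_exposure] = np.nan

    cohort = pd.DataFrame(
        {
            "iid": genotypes.iids,
            "exposure": exposure,
            "mediator": mediator,
            "disease": disease,
            "age": age,
            "sex": sex,
            "deprivation": deprivation,
            "smoking": smoking,
            "diabetes": diabetes,
            **{k: v.astype(int) for k, v in flags.items()},
        }
    ).set_index("iid", drop=False)
    cohort.index.name = None
    return cohort, truth


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the exclusion cascade; tally each row at the first criterion met.

    Returns the filtered cohort and an ordered tally whose values plus the
    filtered row count partition the input row count.
    """
    remaining = np.ones(len(cohort), dtype=bool)
    tally: dict[str, int] = {}
    for criterion in EXCLUSION_ORDER:
        if criterion == "missing_exposure":
            hit = cohort["exposure"].isna().to_numpy()
        else:
            hit = cohort[criterion].to_numpy().astype(bool)
        newly = hit & remaining
        tally[criterion] = int(newly.sum())
        remaining &= ~hit
    return cohort.loc[remaining].copy(), tally


def split_cohort(
    cohort: pd.DataFrame, split_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint two-sample partition of individual ids, deterministic under seed."""
    if not (0.0 < split_fraction < 1.0):
        raise ConfigError("split_fraction must lie in (0, 1)")
    rng = np.random.default_rng([int(seed), 4])
    iids = cohort["iid"].to_numpy()
    perm = rng.permutation(len(iids))
    cut = int(round(split_fraction * len(iids)))
    a, b = np.sort(iids[perm[:cut]]), np.sort(iids[perm[cut:]])
    if min(len(a), len(b)) < 50:
        raise AnalysisError(
            f"two-sample split leaves a sample below 50 individuals "
            f"({len(a)}/{len(b)}): GWAS would be unstable"
        )
    return a, b


def _sumstats_frame(genotypes: GenotypeMatrix, beta, se, p, n) -> pd.DataFrame:
    v = genotypes.variants
    eaf = genotypes.dosages.mean(axis=0) / 2.0
    return pd.DataFrame(
        {
            "SNP": v["SNP"].to_numpy(),
            "CHR": v["CHR"].to_numpy(),
            "BP": v["BP"].to_numpy(),
            "A1": v["A1"].to_numpy(),
            "A2": v["A2"].to_numpy(),
            "EAF": np.clip(eaf, 1e-6, 1 - 1e-6),
            "BETA": beta,
            "SE": se,
            "P": np.clip(p, np.finfo(float).tiny, 1.0),
            "N": n,
        }
    )


def gwas_linear(y: np.ndarray, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant simple linear regression of ``y`` on dosage (vectorised)."""
    from scipy.stats import t as t_dist

    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise AnalysisError("phenotype contains missing values; filter the cohort first")
    n = len(y)
    x = genotypes.dosages
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    if (sxx <= 0).any():
        raise AnalysisError("monomorphic variant in GWAS sample")
    beta = (xc.T @ yc) / sxx
    rss = yc @ yc - beta**2 * sxx
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    return _sumstats_frame(genotypes, beta, se, p, n)


def gwas_logistic(y: np.ndarray, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant logistic regression (intercept + dosage) of a binary trait."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    n = len(y)
    m = genotypes.n_variants
    beta = np.empty(m)
    se = np.empty(m)
    const = np.ones(n)
    for j in range(m):
        X = np.column_stack([const, genotypes.dosages[:, j]])
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=50)
            beta[j], se[j] = fit.params[1], fit.bse[1]
        except Exception:  # separation / non-convergence on a degenerate variant
            beta[j], se[j] = np.nan, np.nan
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * norm.sf(np.abs(z))
    return _sumstats_frame(genotypes, beta, se, p, n)


def make_two_sample_sumstats(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    split_fraction: float = 0.5,
    outcome: str = "disease",
    exposure: str = "exposure",
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample GWAS summary statistics from a disjoint cohort split.

    The exposure GWAS (linear) is run in sample A, the outcome GWAS in sample
    B (logistic for the binary disease, linear otherwise); no individual
    contributes to both tables.
    """
    if cohort[exposure].isna().any():
        raise AnalysisError(
            "exposure has missing values; run apply_exclusions before the GWAS"
        )
    if seed is None:
        seed = 0
    ids_a, ids_b = split_cohort(cohort, split_fraction, seed)
    geno_a = genotypes.subset(ids_a)
    geno_b = genotypes.subset(ids_b)
    exp_stats = gwas_linear(cohort.loc[ids_a, exposure].to_numpy(), geno_a)
    out_vals = cohort.loc[ids_b, outcome].to_numpy()
    if outcome == "disease" or set(np.unique(out_vals)) <= {0.0, 1.0}:
        out_stats = gwas_logistic(out_vals, geno_b)
    else:
        out_stats = gwas_linear(out_vals, geno_b)
    return exp_stats, out_stats


def simulate_summary_instruments(
    n_instruments: int = 20,
    n_per_sample: int = 20_000,
    causal_effect: float = 0.3,
    variance_explained: float = 0.10,
    maf_range: tuple[float, float] = (0.1, 0.4),
    pleiotropy_effect: float = 0.0,
    pleiotropy_ratio: float = 0.0,
    pleiotropic_index: int | None = None,
    exposure_noise: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Summary-level two-sample MR draw for estimator calibration studies.

    Draws per-variant exposure and outcome GWAS estimates directly from their
    sampling distributions for standardised (unit-variance) exposure and
    outcome: the standard construction for MR coverage and outlier-detection
    calibration.  Returns a harmonised-pair style table plus the truth.

    A direct (horizontally pleiotropic) outcome effect is planted on
    ``pleiotropic_index`` (default: the last variant) either as an absolute
    per-allele effect (``pleiotropy_effect``) or as a multiple of that
    variant's mediated effect (``pleiotropy_ratio`` times causal_effect times
    its exposure beta).

    ``exposure_noise=False`` returns the exact exposure betas instead of
    noisy estimates: the no-measurement-error regime under which the IVW
    weights and the pleiotropy test's resampling null are exactly calibrated.
    """
    rng = np.random.default_rng([int(seed), 5])
    mafs = rng.uniform(*maf_range, size=n_instruments)
    var_g = 2.0 * mafs * (1.0 - mafs)
    share = variance_explained / n_instruments
    beta_exp = rng.choice([-1.0, 1.0], n_instruments) * np.sqrt(share / var_g)

    direct = np.zeros(n_instruments)
    idx = n_instruments - 1 if pleiotropic_index is None else pleiotropic_index
    if pleiotropy_effect != 0.0:
        direct[idx] = pleiotropy_effect
    elif pleiotropy_ratio != 0.0:
        direct[idx] = pleiotropy_ratio * causal_effect * beta_exp[idx]

    se_exp = np.sqrt((1.0 - variance_explained) / (n_per_sample * var_g))
    se_out = np.sqrt(1.0 / (n_per_sample * var_g))
    beta_out_true = causal_effect * beta_exp + direct

    pairs = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1:06d}" for i in range(n_instruments)],
            "A1": "A",
            "A2": "G",
            "eaf_exp": mafs,
            "eaf_out": mafs,
            "beta_exp": rng.normal(beta_exp, se_exp) if exposure_noise else beta_exp,
            "se_exp": se_exp,
            "beta_out": rng.normal(beta_out_true, se_out),
            "se_out": se_out,
            "n_exp": n_per_sample,
            "n_out": n_per_sample,
            "flipped": False,
            "palindromic": False,
        }
    )
    truth = {
        "causal_effect": causal_effect,
        "beta_exposure": beta_exp,
        "beta_outcome_direct": direct,
        "pleiotropic_snps": pairs.loc[direct != 0.0, "SNP"].tolist(),
    }
    return pairs, truth
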