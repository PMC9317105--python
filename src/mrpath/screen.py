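"""Stage 1 — agnostic phenome screen with permutation-calibrated p-values.

Each phenome variable is regressed (OLS, covariate-adjusted) as a predictor of
beverage consumption, and the model is gated by an empirical p-value

    P_e = (n + 1) / (s + 1)

where n counts permuted refits whose p-value falls strictly below the observed
one and s is the number of permutations (ties count as not-below).  Only the
outcome vector is shuffled; covariates stay attached to their rows, so the
permutation tests the composite null of no outcome association with the
(predictor, covariate) block.  Permuted refits use the Frisch-Waugh-Lovell
identity, which reproduces the full-model t statistic exactly and vectorises
over permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import AnalysisError, CollinearityError

__all__ = [
    "ScreenConfig",
    "AssocResult",
    "fit_adjusted_linear",
    "empirical_pvalue",
    "variance_explained",
    "screen_phenome",
]

DEFAULT_COVARIATES = ["age", "sex", "deprivation", "smoking", "diabetes"]


@dataclass(frozen=True)
class ScreenConfig:
    covariates: tuple[str, ...] = tuple(DEFAULT_COVARIATES)
    s: int = 10_000
    alpha_empirical: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.s < 1:
            raise AnalysisError("permutation count s must be >= 1")


@dataclass
class AssocResult:
    phenotype: str
    beta: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_empirical: float
    variance_explained_pct: float
    n_used: int
    significant: bool = False

    def as_dict(self):
        return dict(self.__dict__)


@dataclass
class _Design:
    """Pre-computed pieces of one adjusted regression (complete cases only)."""

    y: np.ndarray
    x: np.ndarray
    covariates: np.ndarray  # includes the intercept column
    q: np.ndarray  # orthonormal basis of the covariate block
    x_res: np.ndarray
    sxx: float
    df_resid: int


def _complete_cases(outcome, predictor, covariates: pd.DataFrame):
    mat = pd.concat(
        [pd.Series(np.asarray(outcome, float), name="__y"),
         pd.Series(np.asarray(predictor, float), name="__x"),
         covariates.reset_index(drop=True).astype(float)],
        axis=1,
    )
    keep = ~mat.isna().any(axis=1)
    return mat.loc[keep]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns (beyond the intercept) lying in the span of the others."""
    offenders = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        coef, res, rank, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        fitted = others @ coef
        ss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        rss = np.sum((X[:, j] - fitted) ** 2)
        if ss == 0 or rss < 1e-10 * max(ss, 1.0):
            offenders.append(names[j - 1])
    return offenders


def _build_design(outcome, predictor, covariates: pd.DataFrame) -> _Design:
    mat = _complete_cases(outcome, predictor, covariates)
    n = len(mat)
    k = covariates.shape[1]
    if n < k + 10:
        raise AnalysisError(f"only {n} complete cases for {k} covariates (need >= {k + 10})")
    y = mat["__y"].to_numpy()
    x = mat["__x"].to_numpy()
    C = np.column_stack([np.ones(n), mat.drop(columns=["__y", "__x"]).to_numpy()])
    full = np.column_stack([C, x])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        names = list(covariates.columns) + ["predictor"]
        raise CollinearityError(_collinear_columns(full, names) or names)
    q, _ = np.linalg.qr(C)
    x_res = x - q @ (q.T @ x)
    sxx = float(x_res @ x_res)
    return _Design(y=y, x=x, covariates=C, q=q, x_res=x_res, sxx=sxx,
                   df_resid=n - full.shape[1])


def _slope_stats(design: _Design, y: np.ndarray):
    """Exact full-model slope, SE and two-sided p via FWL residualisation."""
    y_res = y - design.q @ (design.q.T @ y)
    beta = float(design.x_res @ y_res) / design.sxx
    rss = float(y_res @ y_res) - beta**2 * design.sxx
    sigma2 = max(rss, 0.0) / design.df_resid
    se = np.sqrt(sigma2 / design.sxx)
    tval = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * t_dist.sf(abs(tval), df=design.df_resid)
    return beta, se, tval, max(p, np.finfo(float).tiny)


def fit_adjusted_linear(outcome, predictor, covariates: pd.DataFrame):
    """Covariate-adjusted OLS of outcome on predictor.

    Returns ``(beta, se, (ci_low, ci_high), p_observed, n_used)`` with a Wald
    95% CI; complete-case analysis.  Raises :class:`CollinearityError` naming
    the collinear columns on a rank-deficient design.
    """
    design = _build_design(outcome, predictor, covariates)
    beta, se, tval, p = _slope_stats(design, design.y)
    crit = t_dist.ppf(0.975, df=design.df_resid)
    return beta, se, (beta - crit * se, beta + crit * se), p, len(design.y)


def empirical_pvalue(outcome, predictor, covariates: pd.DataFrame,
                     s: int = 10_000, seed: int = 0,
                     chunk: int = 256) -> tuple[float, int, float]:
    """Permutation empirical p-value P_e = (n+1)/(s+1) for the adjusted model.

    Returns ``(p_empirical, n_beat, p_observed)``; ``n_beat`` counts permuted
    p-values strictly below the observed one.  The outcome is permuted whole;
    each permuted fit is the same model form as the observed fit.
    """
    if s < 1:
        raise AnalysisError("permutation count s must be >= 1")
    design = _build_design(outcome, predictor, covariates)
    _, _, t_obs, p_obs = _slope_stats(design, design.y)
    rng = np.random.default_rng(seed)
    n_beat = 0
    n = len(design.y)
    done = 0
    while done < s:
        b = min(chunk, s - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        Y = design.y[idx].T  # (n, b) permuted outcomes
        Yr = Y - design.q @ (design.q.T @ Y)
        betas = (design.x_res @ Yr) / design.sxx
        rss = np.einsum("ij,ij->j", Yr, Yr) - betas**2 * design.sxx
        sigma2 = np.maximum(rss, 0.0) / design.df_resid
        se = np.sqrt(sigma2 / design.sxx)
        tperm = np.divide(betas, se, out=np.full_like(betas, np.inf), where=se > 0)
        # strictly smaller permuted p  <=>  strictly larger |t| (same df)
        n_beat += int((np.abs(tperm) > abs(t_obs)).sum())
        done += b
    return (n_beat + 1) / (s + 1), n_beat, p_obs


def variance_explained(outcome, predictor, covariates: pd.DataFrame) -> float:
    """Percentage of outcome variance explained by the predictor.

    100 * (R2_full - R2_reduced) for the nested pair of OLS models fitted on
    the identical complete-case rows; non-negative by construction.
    """
    design = _build_design(outcome, predictor, covariates)
    y = design.y
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise AnalysisError("outcome has zero variance on complete cases")
    y_res = y - design.q @ (design.q.T @ y)
    rss_reduced = float(y_res @ y_res)
    beta = float(design.x_res @ y_res) / design.sxx
    rss_full = rss_reduced - beta**2 * design.sxx
    return 100.0 * (rss_reduced - rss_full) / tss


def screen_phenome(cohort: pd.DataFrame, phenome: pd.DataFrame,
                   config: ScreenConfig, outcome: str = "exposure") -> pd.DataFrame:
    """Screen every phenome column against beverage consumption.

    The beverage consumption (``outcome`` column of ``cohort``) is the
    regression outcome and each phenotype the predictor, mirroring the
    screen-stage model orientation.  One row per phenotype; deterministic
    under ``config.seed`` (one spawned child seed per phenotype).
    """
    covs = cohort.loc[:, list(config.covariates)]
    y = cohort[outcome]
    children = np.random.SeedSequence(config.seed).spawn(max(len(phenome.columns), 1))
    results = []
    for i, phen in enumerate(phenome.columns):
        x = phenome[phen]
        beta, se, (lo, hi), p_obs, n_used = fit_adjusted_linear(y, x, covs)
        p_emp, _, _ = empirical_pvalue(y, x, covs, s=config.s,
                                       seed=children[i])
        ve = variance_explained(y, x, covs)
        results.append(AssocResult(
            phenotype=phen, beta=beta, ci_low=lo, ci_high=hi,
            p_observed=p_obs, p_empirical=p_emp,
            variance_explained_pct=ve, n_used=n_used,
            significant=p_emp < config.alpha_empirical,
        ))
    return pd.DataFrame([r.as_dict() for r in results])
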