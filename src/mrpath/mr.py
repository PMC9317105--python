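"""Stage 2b — two-sample Mendelian randomisation estimators.

Wald ratio (single instrument), fixed-effect inverse-variance weighting
(multi-instrument), a simulation-based residual-sum-of-squares pleiotropy
test with outlier removal and re-estimation, Benjamini-Hochberg FDR
adjustment, and the single-vs-multi-instrument consistency filter.

The IVW estimator is the weighted mean of per-variant Wald ratios with
weights w_j = beta_exp_j^2 / se_out_j^2, algebraically the zero-intercept
weighted regression of outcome betas on exposure betas with weights
se_out^-2; both formulations are implemented (the regression route through
statsmodels WLS) and cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError

__all__ = [
    "MRResult",
    "PleiotropyReport",
    "wald_ratio",
    "ivw",
    "ivw_regression",
    "pleiotropy_test",
    "outlier_corrected_ivw",
    "fdr_adjust",
    "consistency_filter",
    "format_pvalue",
]


@dataclass
class MRResult:
    method: str  # wald | ivw | ivw_outlier_corrected
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int
    q: float | None = None
    outliers_removed: tuple[str, ...] = ()

    def as_dict(self):
        d = dict(self.__dict__)
        d["outliers_removed"] = ",".join(self.outliers_removed)
        return d


@dataclass
class PleiotropyReport:
    global_rss_p: float
    outlier_p: pd.Series  # Bonferroni-corrected, indexed by SNP
    outliers: tuple[str, ...]
    rss_observed: float
    n_sim: int
    seed: int


def _result(method: str, beta: float, se: float, n_instruments: int,
            outliers: tuple[str, ...] = ()) -> MRResult:
    if beta == 0.0:
        p = 1.0
    elif se > 0:
        p = max(2.0 * norm.sf(abs(beta / se)), np.finfo(float).tiny)
    else:
        p = np.finfo(float).tiny
    return MRResult(
        method=method, beta=beta, se=se,
        ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se,
        p=p, n_instruments=n_instruments, outliers_removed=outliers,
    )


def wald_ratio(pair, second_order: bool = False) -> MRResult:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is the first-order delta form |se_out / beta_exp|; the
    ``second_order`` flag adds the exposure-uncertainty term
    beta_out^2 * se_exp^2 / beta_exp^4 under the square root.
    """
    be, bo, so = float(pair["beta_exp"]), float(pair["beta_out"]), float(pair["se_out"])
    if be == 0.0:
        raise AnalysisError(f"undefined Wald ratio: beta_exp = 0 for {pair.get('SNP', '?')}")
    beta = bo / be
    var = so**2 / be**2
    if second_order:
        var += bo**2 * float(pair["se_exp"]) ** 2 / be**4
    return _result("wald", beta, float(np.sqrt(var)), 1)


def _check_pairs(pairs: pd.DataFrame) -> None:
    zero = pairs.loc[pairs["beta_exp"] == 0.0, "SNP"].tolist()
    if zero:
        raise AnalysisError(f"beta_exp = 0 for variant(s) {zero}")


def ivw(pairs: pd.DataFrame, method_tag: str = "ivw") -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate over harmonised pairs.

    With a single pair this reduces exactly to the Wald ratio.
    """
    if len(pairs) == 0:
        raise AnalysisError("ivw needs at least one harmonised pair")
    _check_pairs(pairs)
    if len(pairs) == 1:
        r = wald_ratio(pairs.iloc[0])
        if method_tag != "ivw":
            r.method = method_tag
        return r
    ratios = pairs["beta_out"].to_numpy() / pairs["beta_exp"].to_numpy()
    w = pairs["beta_exp"].to_numpy() ** 2 / pairs["se_out"].to_numpy() ** 2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return _result(method_tag, beta, se, len(pairs))


def ivw_regression(pairs: pd.DataFrame) -> MRResult:
    """IVW via zero-intercept weighted regression (independent formulation)."""
    import statsmodels.api as sm

    _check_pairs(pairs)
    fit = sm.WLS(
        pairs["beta_out"].to_numpy(),
        pairs["beta_exp"].to_numpy()[:, None],
        weights=1.0 / pairs["se_out"].to_numpy() ** 2,
    ).fit()
    beta = float(fit.params[0])
    # fixed-effect SE: drop the residual-variance scaling WLS applies
    se = float(fit.bse[0] / np.sqrt(fit.scale))
    return _result("ivw", beta, se, len(pairs))


def _loo_ivw(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes on the outcome-beta scale, vectorised."""
    A = np.sum(w * be * bo)
    B = np.sum(w * be * be)
    return (A - w * be * bo) / (B - w * be * be)


def pleiotropy_test(pairs: pd.DataFrame, n_sim: int = 1_000, seed: int = 0) -> PleiotropyReport:
    """Simulation-based global and per-variant horizontal-pleiotropy test.

    Observed RSS = sum_j w_j (beta_out_j - b_{-j} beta_exp_j)^2 with
    w_j = se_out_j^-2 and b_{-j} the leave-one-out IVW slope.  The null
    distribution is built by redrawing beta_out_j ~ N(b_{-j} beta_exp_j,
    se_out_j^2) ``n_sim`` times and recomputing the statistic (including the
    leave-one-out slopes) on each draw; global p = (#{RSS_sim >= RSS_obs}+1) /
    (n_sim+1).  Each variant's observed residual contribution is referred to
    its own simulated distribution and Bonferroni-corrected across
    instruments; corrected p < 0.05 flags an outlier.
    """
    if len(pairs) < 4:
        raise AnalysisError("pleiotropy test needs >= 4 instruments")
    if n_sim < 100:
        raise AnalysisError("n_sim < 100 gives an unstable null distribution")
    _check_pairs(pairs)
    be = pairs["beta_exp"].to_numpy(float)
    bo = pairs["beta_out"].to_numpy(float)
    so = pairs["se_out"].to_numpy(float)
    w = 1.0 / so**2
    m = len(pairs)

    b_loo = _loo_ivw(be, bo, w)
    contrib_obs = w * (bo - b_loo * be) ** 2
    rss_obs = float(np.sum(contrib_obs))

    rng = np.random.default_rng(seed)
    bo_sim = rng.normal(b_loo * be, so, size=(n_sim, m))
    A = bo_sim @ (w * be)  # (n_sim,)
    B = np.sum(w * be * be)
    b_loo_sim = (A[:, None] - w * be * bo_sim) / (B - w * be * be)
    contrib_sim = w * (bo_sim - b_loo_sim * be) ** 2
    rss_sim = contrib_sim.sum(axis=1)

    global_p = (np.sum(rss_sim >= rss_obs) + 1.0) / (n_sim + 1.0)
    per_variant = (np.sum(contrib_sim >= contrib_obs, axis=0) + 1.0) / (n_sim + 1.0)
    corrected = np.minimum(per_variant * m, 1.0)
    snps = pairs["SNP"].to_numpy()
    outliers = tuple(snps[corrected < 0.05])
    return PleiotropyReport(
        global_rss_p=float(global_p),
        outlier_p=pd.Series(corrected, index=snps, name="outlier_p"),
        outliers=outliers,
        rss_observed=rss_obs,
        n_sim=n_sim,
        seed=seed,
    )


def outlier_corrected_ivw(pairs: pd.DataFrame, report: PleiotropyReport) -> MRResult:
    """IVW after removing the pleiotropic outliers flagged in ``report``."""
    unknown = set(report.outliers) - set(pairs["SNP"])
    if unknown:
        raise AnalysisError(f"report flags variants absent from pairs: {sorted(unknown)}")
    keep = pairs.loc[~pairs["SNP"].isin(report.outliers)]
    if len(keep) == 0:
        raise AnalysisError("all instruments flagged as outliers; nothing to estimate")
    result = ivw(keep, method_tag="ivw_outlier_corrected")
    result.method = "ivw_outlier_corrected"
    result.outliers_removed = tuple(report.outliers)
    return result


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise AnalysisError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consistency_filter(
    single: dict[str, MRResult],
    multiple: dict[str, MRResult],
    alpha: float = 0.05,
) -> list[str]:
    """Phenotypes causal in both analyses with the same direction of effect.

    Keeps a phenotype when the multi-instrument result passes q < alpha, the
    single-instrument result passes p < alpha, and the betas agree in sign.
    Phenotypes missing a counterpart are skipped (logged).
    """
    import logging

    log = logging.getLogger(__name__)
    kept = []
    for phen in sorted(set(single) | set(multiple)):
        if phen not in single or phen not in multiple:
            log.info("consistency_filter: %s lacks a counterpart result; skipped", phen)
            continue
        s, m = single[phen], multiple[phen]
        mq = m.q if m.q is not None else m.p
        if s.p < alpha and mq < alpha and np.sign(s.beta) == np.sign(m.beta):
            kept.append(phen)
    return kept


def format_pvalue(p: float) -> str:
    """Display form of a p-value; never prints 0 (floors at '<1e-15')."""
    if p < 1e-15:
        return "<1e-15"
    return f"{p:.3g}"
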