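"""Stage 3 — phenome-wide association of one variant's dosage with binary
ICD10-coded outcomes via adjusted logistic regression, Bonferroni-corrected.

Phenotypes are defined by ICD10 code prefixes (a user-supplied map of group ->
case prefixes plus control-exclusion prefixes).  Cases carry any diagnosis
code matching a case prefix; controls carry no code in the group's combined
case + exclusion prefix set.  Groups below the minimum case count are skipped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .errors import AnalysisError

log = logging.getLogger(__name__)

__all__ = [
    "CaseControlCoding",
    "PhewasResult",
    "code_phenotypes",
    "logistic_assoc",
    "bonferroni_flag",
    "DEMO_PHENOTYPE_MAP",
    "PUBLISHED_RS1229984_PHEWAS",
]

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}")

#: Small built-in demonstration map mirroring the classic alcohol-variant
#: PheWAS categories (alcohol-related disorders, alcoholism, alcoholic liver
#: damage, enthesopathy).  role=case prefixes define cases; role=exclude
#: prefixes additionally remove related diagnoses from the control pool.
DEMO_PHENOTYPE_MAP = pd.DataFrame(
    [
        ("alcohol_related_disorders", "F10", "case"),
        ("alcohol_related_disorders", "K70", "exclude"),
        ("alcoholism", "F102", "case"),
        ("alcoholism", "F10", "exclude"),
        ("alcoholic_liver_damage", "K70", "case"),
        ("alcoholic_liver_damage", "F10", "exclude"),
        ("enthesopathy", "M76", "case"),
        ("enthesopathy", "M77", "exclude"),
    ],
    columns=["group", "prefix", "role"],
)

#: Previously reported UK Biobank PheWAS summary rows for the rs1229984
#: (ADH1B Arg48His) alcohol variant, used for internal-consistency checks
#: (log-odds vs printed odds ratio) and as a worked reference in the docs.
PUBLISHED_RS1229984_PHEWAS = pd.DataFrame(
    [
        ("Alcohol-related disorders", 0.24, 0.16, 0.32, 1.3, 4.87e-10),
        ("Alcoholism", 0.26, 0.16, 0.36, 1.3, 2.52e-8),
        ("Alcoholic liver damage", 0.27, 0.15, 0.39, 1.3, 3.47e-6),
        ("Enthesopathy", -0.06, -0.08, -0.04, 0.9, 1.05e-5),
    ],
    columns=["description", "beta", "ci_low", "ci_high", "odds_ratio", "p"],
)


@dataclass
class CaseControlCoding:
    group: str
    cases: np.ndarray  # individual ids
    controls: np.ndarray
    excluded: np.ndarray  # ids removed from the control pool

    def __post_init__(self):
        if set(self.cases) & set(self.controls):
            raise AnalysisError(f"{self.group}: case/control overlap")


@dataclass
class PhewasResult:
    group: str
    beta: float
    ci_low: float
    ci_high: float
    odds_ratio: float
    p: float
    n_cases: int
    n_controls: int
    significant: bool = False
    note: str = ""

    def as_dict(self):
        return dict(self.__dict__)


def code_phenotypes(
    diagnoses: pd.DataFrame,
    phenotype_map: pd.DataFrame,
    all_ids,
    min_cases: int = 20,
) -> tuple[list[CaseControlCoding], int]:
    """Build case/control codings from a long diagnosis table.

    ``diagnoses`` has columns ``iid`` and ``code``; ``phenotype_map`` has
    columns ``group``, ``prefix``, ``role`` (case|exclude).  Malformed ICD
    codes are skipped and counted (second return value).  Groups with fewer
    than ``min_cases`` cases are skipped with a log entry.
    """
    if phenotype_map["prefix"].astype(str).str.len().eq(0).any():
        raise AnalysisError("phenotype map contains an empty prefix")
    all_ids = np.asarray(all_ids)
    codes = diagnoses["code"].astype(str).str.replace(".", "", regex=False).str.upper()
    ok = codes.str.match(_ICD_RE)
    n_malformed = int((~ok).sum())
    dx = pd.DataFrame({"iid": diagnoses["iid"], "code": codes})[ok.to_numpy()]

    codings = []
    for group, gmap in phenotype_map.groupby("group", sort=True):
        case_prefixes = tuple(gmap.loc[gmap["role"] == "case", "prefix"].astype(str))
        excl_prefixes = tuple(gmap.loc[gmap["role"] == "exclude", "prefix"].astype(str))
        is_case_code = dx["code"].str.startswith(case_prefixes) if case_prefixes else pd.Series(False, index=dx.index)
        related = case_prefixes + excl_prefixes
        is_related = dx["code"].str.startswith(related)
        case_ids = np.intersect1d(np.unique(dx.loc[is_case_code, "iid"]), all_ids)
        related_ids = np.intersect1d(np.unique(dx.loc[is_related, "iid"]), all_ids)
        if len(case_ids) < min_cases:
            log.info("phenotype %s skipped: %d case(s) < floor %d", group, len(case_ids), min_cases)
            continue
        controls = np.setdiff1d(all_ids, related_ids)
        excluded = np.setdiff1d(related_ids, case_ids)
        codings.append(CaseControlCoding(group, case_ids, controls, excluded))
    return codings, n_malformed


def logistic_assoc(
    dosage: pd.Series,
    coding: CaseControlCoding,
    covariates: pd.DataFrame | None = None,
) -> PhewasResult:
    """Adjusted logistic regression of case status on additive dosage.

    Separation or non-convergence yields a flagged result with p = NaN rather
    than an exception, so a phenome loop can continue.
    """
    if len(coding.cases) < 20:
        raise AnalysisError(f"{coding.group}: fewer than 20 cases")
    ids = np.concatenate([coding.cases, coding.controls])
    y = np.concatenate([np.ones(len(coding.cases)), np.zeros(len(coding.controls))])
    g = dosage.loc[ids].to_numpy(float)
    X = [np.ones(len(ids)), g]
    if covariates is not None:
        X.extend(covariates.loc[ids, c].to_numpy(float) for c in covariates.columns)
    X = np.column_stack(X)
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True):
            raise AnalysisError("did not converge")
        beta, se = float(fit.params[1]), float(fit.bse[1])
    except Exception as exc:
        return PhewasResult(
            group=coding.group, beta=np.nan, ci_low=np.nan, ci_high=np.nan,
            odds_ratio=np.nan, p=np.nan, n_cases=len(coding.cases),
            n_controls=len(coding.controls), note=f"separation/non-convergence: {exc}",
        )
    p = max(2.0 * norm.sf(abs(beta / se)), np.finfo(float).tiny)
    return PhewasResult(
        group=coding.group, beta=beta,
        ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se,
        odds_ratio=float(np.exp(beta)), p=p,
        n_cases=len(coding.cases), n_controls=len(coding.controls),
    )


def bonferroni_flag(results: list[PhewasResult], m: int | None = None) -> list[PhewasResult]:
    """Flag results significant at the Bonferroni threshold 0.05 / m.

    ``m`` defaults to the number of phenotypes actually tested (results with a
    finite p), not the number attempted.
    """
    tested = [r for r in results if np.isfinite(r.p)]
    if m is None:
        m = len(tested)
    if m < 1:
        raise AnalysisError("Bonferroni family size must be >= 1")
    for r in results:
        r.significant = bool(np.isfinite(r.p) and r.p < 0.05 / m)
    return results
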