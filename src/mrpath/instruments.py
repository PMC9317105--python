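"""Stage 2a — instrument strength, weak-instrument filtering, LD pruning,
and exposure/outcome harmonisation.

Instrument strength uses the t-statistic forms, which need only (beta, se, n):

    R2 = t^2 / (t^2 + n - 2),   t = beta / se
    F  = (n - 2) * R2 / (1 - R2)        (single-instrument form, so F = t^2)

The allele-frequency form 2*eaf*(1-eaf)*beta^2 is provided as a cross-check
utility.  Variants with F below the threshold (conventionally 10) are weak
instruments and removed; variants in linkage disequilibrium (pairwise
r^2 at or above the threshold, conventionally 0.1) are greedily pruned in
ascending exposure p-value order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError

__all__ = [
    "variant_r2",
    "variant_r2_eaf",
    "f_statistic",
    "instrument_strength",
    "ld_prune",
    "harmonize",
    "PAIR_COLUMNS",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "SNP", "A1", "A2", "eaf_exp", "eaf_out",
    "beta_exp", "se_exp", "beta_out", "se_out",
    "n_exp", "n_out", "flipped", "palindromic",
]


def variant_r2(beta: float, se: float, n: int) -> float:
    """Fraction of exposure variance explained by one variant (t-statistic form)."""
    if n <= 2:
        raise AnalysisError("variant_r2 needs n > 2")
    if not se > 0:
        raise AnalysisError("variant_r2 needs se > 0")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def variant_r2_eaf(beta: float, eaf: float) -> float:
    """Allele-frequency form 2*eaf*(1-eaf)*beta^2 (standardised-trait cross-check)."""
    return 2.0 * eaf * (1.0 - eaf) * beta**2


def f_statistic(r2: float, n: int) -> float:
    """Single-instrument F statistic (n-2)*R2/(1-R2); monotone in both arguments."""
    if not (0.0 <= r2 < 1.0):
        raise AnalysisError("r2 must lie in [0, 1)")
    if n <= 2:
        raise AnalysisError("f_statistic needs n > 2")
    return (n - 2) * r2 / (1.0 - r2)


def instrument_strength(sumstats: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Per-variant R2/F with the weak-instrument verdict.

    Returns one row per input record with columns ``r2``, ``f_stat``,
    ``kept`` and ``reason`` ('' or 'weak').
    """
    out = sumstats.copy()
    out["r2"] = [
        variant_r2(b, s, n) for b, s, n in zip(out["BETA"], out["SE"], out["N"])
    ]
    out["f_stat"] = [f_statistic(r2, n) for r2, n in zip(out["r2"], out["N"])]
    out["kept"] = out["f_stat"] >= f_min
    out["reason"] = np.where(out["kept"], "", "weak")
    return out


def ld_prune(stats: pd.DataFrame, ld: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Greedy LD pruning of an instrument table.

    Variants are visited in ascending exposure p-value (ties: larger F first,
    then lexical id) and kept iff their r^2 with every already-kept variant is
    strictly below ``threshold``.  Input must carry columns ``SNP``, ``P`` and
    ``f_stat``; returns the table with ``kept``/``reason`` updated (removed
    variants get reason 'ld_pruned').  The greedy kept set is maximal: no
    pruned variant can be re-added without violating the threshold.
    """
    missing = [s for s in stats["SNP"] if s not in ld.index]
    if missing:
        raise AnalysisError(f"variant(s) missing from LD matrix: {missing}")
    order = stats.sort_values(
        ["P", "f_stat", "SNP"], ascending=[True, False, True]
    ).index
    kept_ids: list[str] = []
    kept = pd.Series(False, index=stats.index)
    for idx in order:
        snp = stats.at[idx, "SNP"]
        if not kept_ids or (ld.loc[snp, kept_ids].to_numpy() < threshold).all():
            kept_ids.append(snp)
            kept[idx] = True
    out = stats.copy()
    out["kept"] = kept
    out.loc[~kept, "reason"] = "ld_pruned"
    return out


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align exposure and outcome records to a shared effect allele.

    The shared effect allele is canonicalised to the exposure *minor* allele
    (lexically smaller allele on an exact 0.5 frequency tie), which makes the
    output invariant under relabelling (A1/A2 swap with beta negation) of
    either input table.  Outcome records whose alleles are swapped get their
    beta sign and eaf flipped; a strand complement is applied when it resolves
    the match.  Palindromic variants (A/T, C/G) are orientation-checked by
    allele frequency: both eafs must fall outside ``0.5 +/- window`` and agree
    on the minor allele, otherwise the pair is dropped as unharmonizable.

    Returns ``(pairs, dropped)``; harmonising an already-harmonised pair
    changes nothing (idempotence).
    """
    for name, tab in (("exposure", exposure), ("outcome", outcome)):
        if tab["SNP"].duplicated().any():
            dups = tab.loc[tab["SNP"].duplicated(), "SNP"].tolist()
            raise FormatError(f"duplicate variant id(s) in {name} table: {dups}")

    merged = exposure.merge(outcome, on="SNP", suffixes=("_e", "_o"))
    pairs, dropped = [], []
    w = palindromic_eaf_window
    for rec in merged.itertuples(index=False):
        e1, e2 = rec.A1_e.upper(), rec.A2_e.upper()
        o1, o2 = rec.A1_o.upper(), rec.A2_o.upper()
        beta_e, eaf_e = rec.BETA_e, rec.EAF_e
        beta_o, eaf_o = rec.BETA_o, rec.EAF_o

        # canonical exposure orientation: effect allele = minor allele
        if eaf_e > 0.5 or (eaf_e == 0.5 and e1 > e2):
            e1, e2 = e2, e1
            beta_e, eaf_e = -beta_e, 1.0 - eaf_e

        palindromic = _is_palindromic(e1, e2)
        flipped = False
        if {o1, o2} == {e1, e2}:
            pass  # label match (same or swapped order), handled below
        elif not palindromic and {_COMPLEMENT[o1], _COMPLEMENT[o2]} == {e1, e2}:
            o1, o2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
        else:
            dropped.append((rec.SNP, "unharmonizable"))
            continue
        if (o1, o2) == (e2, e1):
            o1, o2 = o2, o1
            beta_o, eaf_o = -beta_o, 1.0 - eaf_o
            flipped = True

        if palindromic:
            # labels cannot fix the strand; orientation must come from eaf
            outside = abs(eaf_e - 0.5) > w and abs(eaf_o - 0.5) > w
            if not (outside and (eaf_e < 0.5) == (eaf_o < 0.5)):
                dropped.append((rec.SNP, "unharmonizable"))
                continue

        pairs.append({
            "SNP": rec.SNP, "A1": e1, "A2": e2,
            "eaf_exp": eaf_e, "eaf_out": eaf_o,
            "beta_exp": beta_e, "se_exp": rec.SE_e,
            "beta_out": beta_o, "se_out": rec.SE_o,
            "n_exp": rec.N_e, "n_out": rec.N_o,
            "flipped": flipped, "palindromic": palindromic,
        })
    pairs_df = pd.DataFrame(pairs, columns=PAIR_COLUMNS)
    dropped_df = pd.DataFrame(dropped, columns=["SNP", "reason"])
    return pairs_df, dropped_df


def pairs_to_tables(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-expand a harmonised-pair table into exposure/outcome record tables.

    Useful for idempotence checks and for feeding a harmonised set back
    through the pipeline.
    """
    base = {
        "SNP": pairs["SNP"], "CHR": "1", "BP": np.arange(1, len(pairs) + 1),
        "A1": pairs["A1"], "A2": pairs["A2"],
    }
    from scipy.stats import norm as _norm

    def table(beta, se, eaf, n):
        z = np.abs(np.asarray(beta) / np.asarray(se))
        p = np.clip(2.0 * _norm.sf(z), np.finfo(float).tiny, 1.0)
        return pd.DataFrame({**base, "EAF": eaf, "BETA": beta, "SE": se,
                             "P": p, "N": n})

    exp = table(pairs["beta_exp"], pairs["se_exp"], pairs["eaf_exp"], pairs["n_exp"])
    out = table(pairs["beta_out"], pairs["se_out"], pairs["eaf_out"], pairs["n_out"])
    return exp, out
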