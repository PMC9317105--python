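"""Read, validate and write the tabular interchange formats.

One GWAS summary dialect is canonical throughout the pipeline: a tab-separated
table with header ``SNP CHR BP A1 A2 EAF BETA SE P N`` ('.' for missing,
positions 1-based, alleles upper-cased on read, biallelic SNPs only).  Other
dialects are mapped onto it via a column-name dictionary at read time.
Result tables carry a '#'-prefixed metadata header block (key: value lines).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import FormatError

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]
_VALID_ALLELES = {"A", "C", "G", "T"}


def _validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into valid records and dropped rows with reasons."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        sel = mask & (reasons == "")
        reasons[sel] = reason

    a1 = df["A1"].astype(str).str.upper()
    a2 = df["A2"].astype(str).str.upper()
    flag(~a1.isin(_VALID_ALLELES) | ~a2.isin(_VALID_ALLELES), "non_snp_allele")
    flag(a1 == a2, "identical_alleles")
    for col in ("EAF", "BETA", "SE", "P", "N"):
        flag(pd.to_numeric(df[col], errors="coerce").isna(), f"missing_{col.lower()}")
    eaf = pd.to_numeric(df["EAF"], errors="coerce")
    se = pd.to_numeric(df["SE"], errors="coerce")
    p = pd.to_numeric(df["P"], errors="coerce")
    flag(~((eaf > 0) & (eaf < 1)), "eaf_out_of_range")
    flag(~(se > 0), "nonpositive_se")
    flag(~((p > 0) & (p <= 1)), "p_out_of_range")

    bad = reasons != ""
    dropped = pd.DataFrame({"SNP": df.loc[bad, "SNP"], "reason": reasons[bad]})
    good = df.loc[~bad].copy()
    good["A1"] = a1[~bad]
    good["A2"] = a2[~bad]
    for col in ("EAF", "BETA", "SE", "P"):
        good[col] = pd.to_numeric(good[col])
    for col in ("BP", "N"):
        good[col] = pd.to_numeric(good[col]).astype(np.int64)

    # Published p-values are often rounded; warn (never fail) if p disagrees
    # with |beta/se| by more than two orders of magnitude.
    if len(good):
        z = (good["BETA"] / good["SE"]).abs()
        p_z = np.clip(2.0 * norm.sf(z), np.finfo(float).tiny, 1.0)
        ratio = np.log10(good["P"]) - np.log10(p_z)
        odd = np.abs(ratio) > 2.0
        if odd.any():
            log.warning(
                "%d record(s) have P inconsistent with |BETA/SE| by >2 orders "
                "of magnitude (first: %s)",
                int(odd.sum()),
                good.loc[odd, "SNP"].iloc[0],
            )
    return good.reset_index(drop=True), dropped.reset_index(drop=True)


def read_sumstats(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    return_dropped: bool = False,
):
    """Read a GWAS summary table, validating every record.

    ``dialect`` maps canonical column names to the file's column names.  Rows
    violating the record invariants are dropped with a logged reason; the drop
    table is returned when ``return_dropped`` is true and is always available
    under ``df.attrs['dropped']``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."], dtype={"CHR": str})
    mapping = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=mapping)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    good, dropped = _validate_sumstats(df[CANONICAL_COLUMNS])
    if len(dropped):
        log.info("%s: dropped %d invalid record(s)", path, len(dropped))
    good.attrs["dropped"] = dropped.to_dict("records")
    if return_dropped:
        return good, dropped
    return good


def write_sumstats(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    write_table(df[CANONICAL_COLUMNS], path, metadata)


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a symmetric r-squared matrix (TSV with id header row and column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise FormatError(f"{path}: LD matrix must be square with matching id labels")
    m = df.to_numpy(dtype=float)
    asym = np.abs(m - m.T).max(initial=0.0)
    if asym > 1e-6:
        raise FormatError(f"{path}: LD matrix asymmetry {asym:.3g} exceeds 1e-6")
    m = 0.5 * (m + m.T)
    if (m < 0).any() or (m > 1 + 1e-12).any():
        raise FormatError(f"{path}: r-squared values must lie in [0, 1]")
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(np.clip(m, 0.0, 1.0), index=df.index, columns=df.columns)


def write_ld_matrix(ld: pd.DataFrame, path: str | Path) -> None:
    ld.to_csv(path, sep="\t", index_label="")


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a result table as TSV with a '#'-prefixed metadata header block."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`; metadata lands in ``attrs``."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."])
    df.attrs["metadata"] = meta
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index(pd.Index(df["iid"]))


def write_raw_dosages(genotypes, path: str | Path) -> None:
    """Write additive dosages as a plink-style .raw table (FID, IID, id_A1)."""
    cols = {
        "FID": genotypes.iids,
        "IID": genotypes.iids,
    }
    names = genotypes.variants["SNP"] + "_" + genotypes.variants["A1"]
    for j, name in enumerate(names):
        cols[name] = genotypes.dosages[:, j].astype(int)
    pd.DataFrame(cols).to_csv(path, sep=" ", index=False)


def read_raw_dosages(path: str | Path) -> pd.DataFrame:
    """Read a plink-style .raw additive table; columns are variant ids, index IID.

    The trailing ``_A1`` counted-allele suffix is preserved in ``attrs`` and
    stripped from the column names.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if "IID" not in df.columns:
        raise FormatError(f"{path}: .raw table must carry an IID column")
    df = df.set_index("IID")
    df = df.drop(columns=[c for c in ("FID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df])
    counted = {}
    renames = {}
    for col in df.columns:
        snp, _, allele = col.rpartition("_")
        if snp and allele in _VALID_ALLELES:
            renames[col] = snp
            counted[snp] = allele
    df = df.rename(columns=renames)
    df.attrs["counted_allele"] = counted
    return df
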