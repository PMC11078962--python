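"""Reading, validation and writing of GWAS summary statistics.

Summary statistics arrive as delimited text with one row per variant. The
native dialect is tab-separated with a header; a ``column_map`` adapts other
headers (e.g. FinnGen-style ``rsids``/``pval`` or metabolomics-server exports)
onto the canonical column names without per-source parsers.

Canonical columns: ``snp``, ``chrom``, ``pos``, ``effect_allele``,
``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``. Mandatory:
snp, effect_allele, other_allele, beta, se, pval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDatasetError, SchemaError

MANDATORY = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL = ("chrom", "pos", "eaf", "n")
VALID_ALLELES = frozenset("ACGT")

#: absolute tolerance for the p-value vs z-score consistency flag
PZ_TOLERANCE = 0.01


@dataclass
class TraitMeta:
    """Metadata for one trait's summary statistics."""

    trait_id: str
    trait_label: str = ""
    trait_type: str = "quantitative"  # or "binary"
    n_total: int | None = None
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.n_cases is not None and self.trait_type != "binary":
            raise ValueError("n_cases only meaningful for binary traits")
        if not self.trait_label:
            self.trait_label = self.trait_id


@dataclass
class LoadReport:
    """Bookkeeping for one file read: valid + invalid + duplicate = data lines."""

    n_lines: int = 0
    n_valid: int = 0
    n_invalid: int = 0
    n_duplicate: int = 0
    pz_flagged: list[str] = field(default_factory=list)


@dataclass
class SummaryDataset:
    """One trait's per-variant association records.

    ``table`` holds the canonical columns; ``snp`` values are unique.
    """

    meta: TraitMeta
    table: pd.DataFrame
    load_report: LoadReport | None = None

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "SummaryDataset":
        return SummaryDataset(self.meta, self.table.loc[mask].reset_index(drop=True))

    def lookup(self, snp_ids) -> pd.DataFrame:
        """Rows for the given snp ids, indexed by snp (missing ids absent)."""
        idx = self.table.set_index("snp")
        return idx.loc[idx.index.intersection(snp_ids)]


def _valid_allele(a) -> bool:
    return isinstance(a, str) and len(a) == 1 and a in VALID_ALLELES


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    """Apply per-record invariants; return (valid unique rows, report).

    Rows violating an invariant are dropped; rows whose p-value disagrees
    with the two-sided normal p implied by beta/se beyond ``PZ_TOLERANCE``
    are kept but flagged (unit mistakes are reported, never auto-corrected).
    """
    report = LoadReport(n_lines=len(df))
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=ea, other_allele=oa)

    ok = (
        ea.map(_valid_allele)
        & oa.map(_valid_allele)
        & (ea != oa)
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
    )
    if "eaf" in df.columns:
        eaf = df["eaf"]
        ok &= eaf.isna() | ((eaf >= 0) & (eaf <= 1))
    valid = df.loc[ok.fillna(False)]
    report.n_invalid = len(df) - len(valid)

    dup = valid["snp"].duplicated(keep="first")
    report.n_duplicate = int(dup.sum())
    valid = valid.loc[~dup].reset_index(drop=True)
    report.n_valid = len(valid)

    z = np.abs(valid["beta"] / valid["se"])
    p_implied = 2.0 * stats.norm.sf(z)
    flag = np.abs(valid["pval"].to_numpy(float) - p_implied) > PZ_TOLERANCE
    report.pz_flagged = list(valid.loc[flag, "snp"])
    return valid, report


def read_sumstats(
    path,
    trait_meta: TraitMeta,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> SummaryDataset:
    """Read one trait's summary statistics from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    trait_meta
        Trait identity and sample sizes.
    column_map
        Maps canonical names to the file's header names, e.g.
        ``{"snp": "rsids", "pval": "pval"}``. Canonical names already present
        in the header need not be mapped.
    sep
        Field delimiter (tab by default).
    """
    raw = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    rename = {}
    for canon in MANDATORY + OPTIONAL:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in MANDATORY:
            raise SchemaError(f"column for {canon!r} not found in {path}")
    df = raw.rename(columns=rename)
    keep = [c for c in MANDATORY + OPTIONAL if c in df.columns]
    df = df[keep].copy()
    df["snp"] = df["snp"].astype(str)
    for col in ("beta", "se", "pval", "eaf"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    valid, report = validate_records(df)
    if len(valid) == 0:
        raise EmptyDatasetError(f"no valid rows in {path}")
    return SummaryDataset(trait_meta, valid.reset_index(drop=True), report)


def write_results_table(rows, path) -> None:
    """Write result records as tab-separated text with full float precision.

    ``rows`` may be a DataFrame or an iterable of mappings sharing a schema.
    Values round-trip through ``pd.read_csv`` unchanged (floats use repr).
    Unreliable/missing values should already be the string "NA".
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_sumstats(ds: SummaryDataset, path) -> None:
    """Write a dataset in the native tab-separated dialect (read round-trips)."""
    ds.table.to_csv(path, sep="\t", index=False)
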