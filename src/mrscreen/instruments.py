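"""Instrument selection for two-sample MR.

Instruments for a metabolite are exposure-associated variants passing, in
order: a significance filter (p < 1e-5), greedy LD clumping (r² < 0.01
within 500 kb), a per-SNP strength filter (F > 10), and exclusion of
variants associated with the outcome (p < 1e-5). Metabolites retaining
fewer than ``min_ivs`` instruments (default 4) are flagged insufficient
rather than analyzed.

Pairwise LD is consumed as an explicit r² table; without one, clumping is
distance-only within the window (conservative: one SNP per window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, MrScreenError
from .sumstats import SummaryDataset


class LDTable:
    """Symmetric pairwise-r² lookup backed by a 3-column table (snp_a, snp_b, r2)."""

    def __init__(self, pairs: pd.DataFrame | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs is not None:
            for a, b, r2 in pairs[["snp_a", "snp_b", "r2"]].itertuples(index=False):
                self._r2[(str(a), str(b))] = float(r2)
                self._r2[(str(b), str(a))] = float(r2)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LDTable":
        return cls(pd.read_csv(path, sep=sep))

    def r2(self, a: str, b: str) -> float | None:
        """Pairwise r², or None when the pair is not tabulated (treated as independent)."""
        return self._r2.get((a, b))


@dataclass
class ClumpConfig:
    """Thresholds for instrument selection and clumping."""

    p_threshold: float = 1e-5
    r2_max: float = 0.01
    window_bp: int = 500_000
    ld_source: LDTable | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigError("p_threshold must lie in (0,1)")
        if not (0 < self.r2_max < 1):
            raise ConfigError("r2_max must lie in (0,1)")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")


@dataclass
class InstrumentSet:
    """Surviving instruments for one exposure, with per-SNP strength."""

    exposure_id: str
    table: pd.DataFrame  # canonical sumstats columns + r2_explained, f_stat
    excluded: dict[str, str] = field(default_factory=dict)  # snp -> reason

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_r2(self) -> float:
        return float(self.table["r2_explained"].sum())


@dataclass
class InsufficientInstruments:
    """Marker: fewer than min_ivs instruments survived selection."""

    exposure_id: str
    count: int


def filter_by_pvalue(ds: SummaryDataset, threshold: float) -> SummaryDataset:
    """Records with exposure p strictly below ``threshold``."""
    if not (0 < threshold < 1):
        raise ConfigError("threshold must lie in (0,1)")
    return ds.subset(ds.table["pval"] < threshold)


def clump(ds: SummaryDataset, cfg: ClumpConfig) -> SummaryDataset:
    """Greedy clumping by ascending p-value (ties broken by snp id).

    A candidate is dropped when it lies within ``window_bp`` of an
    already-retained SNP on the same chromosome and either no LD source is
    configured (distance-only mode) or its r² with that SNP is >= ``r2_max``.
    """
    t = ds.table
    if len(t) == 0:
        return ds.subset(np.zeros(0, dtype=bool))
    if t["chrom"].isna().any() or t["pos"].isna().any():
        raise MrScreenError("clumping requires chrom and pos on every record")
    order = t.sort_values(["pval", "snp"], kind="mergesort").index
    kept: list[int] = []
    kept_by_chrom: dict[str, list[tuple[float, str]]] = {}
    for i in order:
        chrom = str(t.at[i, "chrom"])
        pos = float(t.at[i, "pos"])
        snp = t.at[i, "snp"]
        drop = False
        for kpos, ksnp in kept_by_chrom.get(chrom, ()):
            if abs(pos - kpos) < cfg.window_bp:
                if cfg.ld_source is None:
                    drop = True
                    break
                r2 = cfg.ld_source.r2(snp, ksnp)
                if r2 is not None and r2 >= cfg.r2_max:
                    drop = True
                    break
        if not drop:
            kept.append(i)
            kept_by_chrom.setdefault(chrom, []).append((pos, snp))
    mask = t.index.isin(kept)
    return ds.subset(pd.Series(mask, index=t.index))


def per_snp_strength(beta: float, se: float, n: float) -> tuple[float, float]:
    """(r² explained, F statistic) for one variant.

    F = (beta/se)²; r² = F / (F + n - 2), the first-order equivalence used
    with summary statistics.
    """
    if n is None or not np.isfinite(n) or n <= 2:
        raise MrScreenError("sample size must exceed 2")
    if se <= 0:
        raise MrScreenError("se must be positive")
    f = (beta / se) ** 2
    return f / (f + n - 2.0), f


def exclude_outcome_associated(
    ivs: pd.DataFrame, outcome: SummaryDataset, threshold: float
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop instruments associated with the outcome (p < threshold).

    Instruments absent from the outcome dataset cannot be harmonized and are
    dropped with reason ``not_in_outcome``.
    """
    if not (0 < threshold < 1):
        raise ConfigError("threshold must lie in (0,1)")
    out_p = outcome.table.set_index("snp")["pval"]
    excluded: dict[str, str] = {}
    keep = []
    for snp in ivs["snp"]:
        if snp not in out_p.index:
            excluded[snp] = "not_in_outcome"
            keep.append(False)
        elif out_p[snp] < threshold:
            excluded[snp] = "outcome_associated"
            keep.append(False)
        else:
            keep.append(True)
    return ivs.loc[keep].reset_index(drop=True), excluded


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    cfg: ClumpConfig | None = None,
    f_min: float = 10.0,
    min_ivs: int = 4,
) -> InstrumentSet | InsufficientInstruments:
    """Full selection pipeline for one exposure.

    Composes significance filter → clumping → F filter → outcome-association
    exclusion; returns an :class:`InsufficientInstruments` flag carrying the
    surviving count when fewer than ``min_ivs`` remain.
    """
    cfg = cfg or ClumpConfig()
    if min_ivs < 1:
        raise ConfigError("min_ivs must be >= 1")
    sig = filter_by_pvalue(exposure, cfg.p_threshold)
    clumped = clump(sig, cfg)
    t = clumped.table.sort_values("snp", kind="mergesort").reset_index(drop=True)

    excluded: dict[str, str] = {}
    if len(t):
        n_col = t["n"].to_numpy(float)
        if np.isnan(n_col).any() and exposure.meta.n_total is not None:
            n_col = np.where(np.isnan(n_col), exposure.meta.n_total, n_col)
        strength = [
            per_snp_strength(b, s, n)
            for b, s, n in zip(t["beta"], t["se"], n_col)
        ]
        t["r2_explained"] = [r2 for r2, _ in strength]
        t["f_stat"] = [f for _, f in strength]
        weak = t["f_stat"] <= f_min
        for snp in t.loc[weak, "snp"]:
            excluded[snp] = "weak_instrument"
        t = t.loc[~weak].reset_index(drop=True)
    else:
        t = t.assign(r2_explained=pd.Series(dtype=float), f_stat=pd.Series(dtype=float))

    t, out_excl = exclude_outcome_associated(t, outcome, cfg.p_threshold)
    excluded.update(out_excl)
    if len(t) < min_ivs:
        return InsufficientInstruments(exposure.meta.trait_id, len(t))
    return InstrumentSet(exposure.meta.trait_id, t, excluded)
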