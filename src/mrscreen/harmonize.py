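"""Allele harmonization of exposure instruments against outcome records.

Both GWAS must express each SNP's effect on the same effect allele before
Wald ratios mean anything. For each instrument found in the outcome:

* identical allele pair → kept as-is (``aligned``);
* swapped pair (effect ↔ other) → outcome beta negated, frequency
  complemented (``flipped``);
* incompatible allele sets (e.g. A/G vs A/C) → ``dropped_mismatch``;
* palindromic pair (A/T or C/G), whose strand cannot be resolved from
  alleles alone → dropped when either source's effect-allele frequency is
  missing or sits in the ambiguity band around 0.5 (default [0.40, 0.60]),
  otherwise oriented by matching which side of 0.5 the frequencies fall on.

Instruments absent from the outcome are flagged ``not_in_outcome``. Strand
complements of non-palindromic pairs are not inferred: with no strand
column, a complemented pair is indistinguishable from a genuinely
different variant and is treated as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyHarmonizationError
from .instruments import InstrumentSet
from .sumstats import SummaryDataset

ALIGNED = "aligned"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"
NOT_IN_OUTCOME = "not_in_outcome"

_PALINDROME_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Aligned per-SNP effect pairs for one exposure–outcome analysis."""

    exposure_id: str
    outcome_id: str
    snp: np.ndarray  # retained SNP ids, length J
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    flags: dict[str, str] = field(default_factory=dict)  # every instrument

    @property
    def n_snp(self) -> int:
        return len(self.snp)

    def drop(self, indices) -> "HarmonizedSet":
        """Copy with the given positional indices removed (flags unchanged)."""
        keep = np.setdiff1d(np.arange(self.n_snp), np.asarray(indices, dtype=int))
        return HarmonizedSet(
            self.exposure_id, self.outcome_id, self.snp[keep],
            self.beta_x[keep], self.se_x[keep], self.beta_y[keep],
            self.se_y[keep], dict(self.flags),
        )


def from_arrays(beta_x, se_x, beta_y, se_y, snp=None,
                exposure_id="exposure", outcome_id="outcome") -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (already aligned)."""
    beta_x = np.asarray(beta_x, dtype=float)
    if snp is None:
        snp = np.array([f"snp{i}" for i in range(len(beta_x))])
    return HarmonizedSet(
        exposure_id, outcome_id, np.asarray(snp),
        beta_x, np.asarray(se_x, dtype=float),
        np.asarray(beta_y, dtype=float), np.asarray(se_y, dtype=float),
        {str(s): ALIGNED for s in snp},
    )


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROME_PAIRS


def harmonize(
    ivs: InstrumentSet | SummaryDataset,
    outcome: SummaryDataset,
    maf_band: tuple[float, float] = (0.40, 0.60),
    strict_palindromes: bool = False,
) -> HarmonizedSet:
    """Align instrument and outcome records onto a shared effect-allele frame.

    ``maf_band`` is the ambiguity band on the effect-allele-frequency scale;
    palindromic SNPs whose frequency (either source) falls inside it, or is
    missing, are dropped. ``strict_palindromes`` drops all palindromes.
    """
    exp_t = ivs.table
    exposure_id = ivs.exposure_id if isinstance(ivs, InstrumentSet) else ivs.meta.trait_id
    out_t = outcome.table.set_index("snp")
    lo, hi = maf_band
    flags: dict[str, str] = {}
    rows = []
    for row in exp_t.itertuples(index=False):
        snp = row.snp
        if snp not in out_t.index:
            flags[snp] = NOT_IN_OUTCOME
            continue
        o = out_t.loc[snp]
        ea_x, oa_x = row.effect_allele, row.other_allele
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        if {ea_x, oa_x} != {ea_y, oa_y}:
            flags[snp] = DROPPED_MISMATCH
            continue
        # orient the outcome onto the exposure's effect allele
        if (ea_y, oa_y) == (ea_x, oa_x):
            beta_y, eaf_y, flag = o["beta"], o["eaf"], ALIGNED
        else:  # swapped labels
            beta_y, eaf_y, flag = -o["beta"], 1.0 - o["eaf"], FLIPPED
        if _is_palindromic(ea_x, oa_x):
            eaf_x = row.eaf
            ambiguous = (
                strict_palindromes
                or eaf_x is None or not np.isfinite(eaf_x)
                or eaf_y is None or not np.isfinite(eaf_y)
                or lo <= eaf_x <= hi
                or lo <= eaf_y <= hi
            )
            if ambiguous:
                flags[snp] = DROPPED_PALINDROMIC
                continue
            # label orientation is meaningless across strands; use frequency sides
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                beta_y = -beta_y
                flag = FLIPPED if flag == ALIGNED else ALIGNED
        flags[snp] = flag
        rows.append((snp, row.beta, row.se, beta_y, o["se"]))
    if not rows:
        raise EmptyHarmonizationError(
            f"no SNPs retained harmonizing {exposure_id} vs {outcome.meta.trait_id}"
        )
    snps, bx, sx, by, sy = map(np.array, zip(*rows))
    return HarmonizedSet(
        exposure_id, outcome.meta.trait_id, snps,
        bx.astype(float), sx.astype(float), by.astype(float), sy.astype(float),
        flags,
    )
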