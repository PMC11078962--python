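"""LD score regression: SNP heritability and cross-trait genetic correlation.

Under a polygenic model, the expected chi-square of SNP j grows linearly
with its LD score ell_j: E[chi²_j] = 1 + n_j h² ell_j / M (+ an intercept
offset absorbing confounding/stratification). Regressing chi² on ell and
rescaling the slope by M / mean(n) yields h²; regressing z1·z2 on ell
yields the genetic covariance and, normalized by the heritabilities, the
genetic correlation r_g. Standard errors come from a delete-one block
jackknife over contiguous SNP blocks. Estimates whose jackknife fails or
whose value is implausible are flagged unreliable and serialized as NA,
mirroring common reporting practice.

LD scores are consumed as input (2-column delimited: snp, l2); computing
them from a reference panel is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InsufficientOverlapError

H2_RANGE = (-0.5, 1.5)
RG_SOFT_BOUND = 1.25


@dataclass
class LdscInput:
    """Aligned per-SNP z-statistics, LD scores and sample sizes for one trait."""

    snp: np.ndarray
    z: np.ndarray
    ell: np.ndarray
    n: np.ndarray
    m: int  # total SNPs scaling h2

    def __post_init__(self) -> None:
        self.snp = np.asarray(self.snp)
        self.z = np.asarray(self.z, dtype=float)
        self.ell = np.asarray(self.ell, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if not (len(self.snp) == len(self.z) == len(self.ell) == len(self.n)):
            raise ValueError("all arrays must share a length")
        if (self.ell < 0).any():
            raise ValueError("LD scores must be non-negative")
        if self.m < len(self.snp):
            raise ValueError("m must be at least the number of SNPs")


@dataclass
class LdscResult:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    h2_pval: float
    reliable: bool


@dataclass
class RgResult:
    rg: float
    rg_se: float
    rg_pval: float
    gencov: float
    reliable: bool


def read_ld_scores(path, sep: str = "\t") -> pd.DataFrame:
    """Read a (snp, l2) LD-score table."""
    df = pd.read_csv(path, sep=sep)
    if "snp" not in df.columns or "l2" not in df.columns:
        raise ValueError("LD-score file needs 'snp' and 'l2' columns")
    return df[["snp", "l2"]]


def _block_bounds(length: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, length, n_blocks + 1).astype(int)


def _wls_blocks(x, y, w, bounds):
    """Weighted-regression sufficient statistics per jackknife block.

    Returns an array (n_blocks, 5) of [Sw, Swx, Swy, Swxx, Swxy] so that
    full-data and delete-one-block fits are sums/differences of rows.
    """
    n_blocks = len(bounds) - 1
    sums = np.empty((n_blocks, 5))
    for b in range(n_blocks):
        s = slice(bounds[b], bounds[b + 1])
        xw, yw, ww = x[s], y[s], w[s]
        sums[b] = [ww.sum(), (ww * xw).sum(), (ww * yw).sum(),
                   (ww * xw * xw).sum(), (ww * xw * yw).sum()]
    return sums


def _fit_from_sums(s):
    sw, swx, swy, swxx, swxy = s
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return intercept, slope


def _jackknife(values: np.ndarray) -> float:
    """Delete-one jackknife SE from the deleted-block estimates."""
    b = len(values)
    mean = values.mean()
    return float(np.sqrt((b - 1) / b * np.sum((values - mean) ** 2)))


def _resolve_blocks(length: int, n_blocks: int) -> int:
    return max(2, min(n_blocks, length // 2))


def estimate_h2(inp: LdscInput, n_blocks: int = 200) -> LdscResult:
    """SNP heritability by two-step weighted LD score regression.

    Step 1 fits chi² ~ ell by OLS to get a provisional h²; step 2 reweights
    each SNP by 1/[ell·(1 + n h² ell/M)²] (ell floored at 1, h² clipped to
    [0, 1] inside the weights) and refits. h² = slope · M / mean(n); SEs by
    delete-one block jackknife. The block count auto-shrinks to
    floor(length/2) for small inputs.
    """
    length = len(inp.snp)
    if length < 4:
        raise InsufficientDataError("LDSC needs at least 4 SNPs")
    n_blocks = _resolve_blocks(length, n_blocks)
    chi2 = inp.z**2
    ell = inp.ell
    nbar = inp.n.mean()
    scale = inp.m / nbar

    # step 1: OLS
    ones = np.ones(length)
    bounds = _block_bounds(length, n_blocks)
    s1 = _wls_blocks(ell, chi2, ones, bounds).sum(axis=0)
    _, slope1 = _fit_from_sums(s1)
    h2_0 = float(np.clip(slope1 * scale, 0.0, 1.0))

    # step 2: heteroskedasticity weights
    ell_f = np.maximum(ell, 1.0)
    w = 1.0 / (ell_f * (1.0 + inp.n * h2_0 * ell / inp.m) ** 2)
    sums = _wls_blocks(ell, chi2, w, bounds)
    total = sums.sum(axis=0)
    intercept, slope = _fit_from_sums(total)
    h2 = float(slope * scale)

    h2_del = np.empty(n_blocks)
    int_del = np.empty(n_blocks)
    for b in range(n_blocks):
        icpt_b, slope_b = _fit_from_sums(total - sums[b])
        h2_del[b] = slope_b * scale
        int_del[b] = icpt_b
    h2_se = _jackknife(h2_del)
    int_se = _jackknife(int_del)
    ok = np.isfinite(h2_se) and h2_se > 0 and H2_RANGE[0] <= h2 <= H2_RANGE[1]
    pval = float(2.0 * stats.norm.sf(abs(h2) / h2_se)) if ok else float("nan")
    return LdscResult(h2, h2_se, float(intercept), int_se, pval, bool(ok))


def _align(inp1: LdscInput, inp2: LdscInput):
    common, i1, i2 = np.intersect1d(inp1.snp, inp2.snp, return_indices=True)
    if len(common) < 4:
        raise InsufficientOverlapError("fewer than 4 shared SNPs")
    take = lambda inp, idx: LdscInput(  # noqa: E731
        inp.snp[idx], inp.z[idx], inp.ell[idx], inp.n[idx], inp.m
    )
    return take(inp1, i1), take(inp2, i2)


def estimate_rg(inp1: LdscInput, inp2: LdscInput, n_blocks: int = 200) -> RgResult:
    """Genetic correlation by cross-trait LD score regression.

    Regresses z1·z2 on ell over the SNP intersection; the slope times
    M / sqrt(mean n1 · mean n2) is the genetic covariance, normalized by
    the per-trait heritabilities (estimated on the same intersection) to
    give r_g. The intercept is estimated, not constrained, so sample
    overlap between the two studies is absorbed rather than assumed away.
    The jackknife re-derives r_g in full on every block deletion.
    """
    a, b = _align(inp1, inp2)
    length = len(a.snp)
    n_blocks = _resolve_blocks(length, n_blocks)
    bounds = _block_bounds(length, n_blocks)
    scale_cov = a.m / np.sqrt(a.n.mean() * b.n.mean())

    h2_1 = estimate_h2(a, n_blocks)
    h2_2 = estimate_h2(b, n_blocks)

    # cross-regression weights: symmetric analogue of the h2 weights
    ell_f = np.maximum(a.ell, 1.0)
    c1 = 1.0 + a.n * max(h2_1.h2, 0.0) * a.ell / a.m
    c2 = 1.0 + b.n * max(h2_2.h2, 0.0) * b.ell / b.m
    w = 1.0 / (ell_f * c1 * c2)

    y = a.z * b.z
    sums = _wls_blocks(a.ell, y, w, bounds)
    total = sums.sum(axis=0)
    _, slope = _fit_from_sums(total)
    gencov = float(slope * scale_cov)

    usable = h2_1.reliable and h2_2.reliable and h2_1.h2 > 0 and h2_2.h2 > 0
    if not usable:
        return RgResult(float("nan"), float("nan"), float("nan"), gencov, False)
    rg = gencov / np.sqrt(h2_1.h2 * h2_2.h2)

    # jackknife the whole ratio: slope and both h2 fits per deletion
    chi1 = a.z**2
    chi2_arr = b.z**2
    w1 = 1.0 / (ell_f * c1**2)
    w2 = 1.0 / (ell_f * c2**2)
    sums1 = _wls_blocks(a.ell, chi1, w1, bounds)
    sums2 = _wls_blocks(a.ell, chi2_arr, w2, bounds)
    t1, t2 = sums1.sum(axis=0), sums2.sum(axis=0)
    scale1, scale2 = a.m / a.n.mean(), b.m / b.n.mean()
    rg_del = np.empty(n_blocks)
    for blk in range(n_blocks):
        _, sl = _fit_from_sums(total - sums[blk])
        _, sl1 = _fit_from_sums(t1 - sums1[blk])
        _, sl2 = _fit_from_sums(t2 - sums2[blk])
        h1b, h2b = sl1 * scale1, sl2 * scale2
        if h1b <= 0 or h2b <= 0:
            rg_del[blk] = np.nan
        else:
            rg_del[blk] = (sl * scale_cov) / np.sqrt(h1b * h2b)
    if np.isnan(rg_del).any():
        return RgResult(float(rg), float("nan"), float("nan"), gencov, False)
    rg_se = _jackknife(rg_del)
    ok = np.isfinite(rg_se) and rg_se > 0 and abs(rg) <= RG_SOFT_BOUND
    pval = float(2.0 * stats.norm.sf(abs(rg) / rg_se)) if ok else float("nan")
    return RgResult(float(rg), rg_se, pval, gencov, bool(ok))


def ldsc_input_from_sumstats(ds, ld_scores: pd.DataFrame, m: int | None = None) -> LdscInput:
    """Build an LDSC input from a summary dataset and an LD-score table.

    z is derived as beta/se; SNPs missing an LD score are dropped; M
    defaults to the LD-score table's size.
    """
    t = ds.table.merge(ld_scores, on="snp", how="inner")
    n = t["n"].to_numpy(float)
    if np.isnan(n).any() and ds.meta.n_total is not None:
        n = np.where(np.isnan(n), ds.meta.n_total, n)
    return LdscInput(
        t["snp"].to_numpy(), (t["beta"] / t["se"]).to_numpy(float),
        t["l2"].to_numpy(float), n, m if m is not None else len(ld_scores),
    )
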