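"""Causal-effect estimators for two-sample MR on harmonized summary data.

All estimators combine per-SNP Wald ratios (outcome effect / exposure
effect). The workhorse is the multiplicative random-effects IVW estimator:
a zero-intercept weighted regression of outcome on exposure effects whose
standard error is inflated by the overdispersion implied by Cochran's Q.
MR-Egger adds a free intercept (directional pleiotropy); the weighted
median is consistent when valid instruments carry at least half the
weight; the mode estimators take the peak of a kernel-smoothed density of
the ratios. Binary outcomes are on the log-odds scale, so every estimate
is also reported as an odds ratio with a 95% Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientSnpsError
from .harmonize import HarmonizedSet

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class MREstimate:
    """One method's causal estimate on the beta (log-odds) and OR scales."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))


@dataclass
class EggerIntercept:
    estimate: float
    se: float
    pval: float


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0


def wald_ratios(H: HarmonizedSet, se_order: str = "first"):
    """Per-SNP causal ratios and their standard errors.

    SNPs with zero exposure effect are excluded (their ratio is undefined);
    the returned mask marks the retained SNPs. ``se_order`` "second" adds
    the exposure-uncertainty term to the delta-method variance.
    """
    mask = H.beta_x != 0
    if not mask.any():
        raise DegenerateInputError("all exposure effects are zero")
    bx, by = H.beta_x[mask], H.beta_y[mask]
    sy, sx = H.se_y[mask], H.se_x[mask]
    ratio = by / bx
    if se_order == "second":
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return ratio, se, mask


def _ivw_fit(bx, by, sy):
    """Zero-intercept WLS slope, Q and SE with multiplicative overdispersion.

    Returns (beta, se, Q, phi). Valid for J >= 1 (J = 1 gives the Wald
    ratio with phi = 1).
    """
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    q = float(np.sum(w * (by - beta * bx) ** 2))
    j = len(bx)
    phi = max(1.0, q / (j - 1)) if j > 1 else 1.0
    se = float(np.sqrt(phi / denom))
    return beta, se, q, phi


def ivw_mre(H: HarmonizedSet) -> MREstimate:
    """Multiplicative random-effects IVW estimate (requires J >= 2)."""
    if H.n_snp < 2:
        raise InsufficientSnpsError("IVW requires at least 2 SNPs")
    beta, se, _, _ = _ivw_fit(H.beta_x, H.beta_y, H.se_y)
    return MREstimate("ivw", beta, se, _normal_p(beta, se), H.n_snp)


def ivw_single(H: HarmonizedSet) -> MREstimate:
    """Internal single-SNP path: IVW degenerates to the Wald ratio."""
    beta, se, _, _ = _ivw_fit(H.beta_x, H.beta_y, H.se_y)
    return MREstimate("wald", beta, se, _normal_p(beta, se), H.n_snp)


def mr_egger(H: HarmonizedSet) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression: WLS of beta_y on beta_x with a free intercept.

    Instruments are oriented so all exposure effects are non-negative
    (sign-flipping beta pairs jointly leaves the causal slope invariant but
    makes the intercept interpretable as average directional pleiotropy).
    The slope SE carries the multiplicative overdispersion factor (floored at
    1); the intercept SE uses the unfloored WLS dispersion so its t(J-2) test
    is exactly calibrated under the null. P-values use the t distribution.
    """
    j = H.n_snp
    if j < 3:
        raise InsufficientSnpsError("MR-Egger requires at least 3 SNPs")
    sign = np.where(H.beta_x < 0, -1.0, 1.0)
    bx, by, sy = sign * H.beta_x, sign * H.beta_y, H.se_y
    w = 1.0 / sy**2
    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx**2), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    sigma2 = q / (j - 2)  # WLS dispersion
    phi = max(1.0, sigma2)  # floored only for the slope's (reported) SE
    se_slope = float(np.sqrt(phi * sw / det))
    # intercept test uses the unfloored dispersion: exact t(J-2) under the null
    se_int = float(np.sqrt(sigma2 * swxx / det))
    tdist = stats.t(df=j - 2)
    p_slope = float(2.0 * tdist.sf(abs(slope) / se_slope))
    if se_int > 0:
        p_int = float(2.0 * tdist.sf(abs(intercept) / se_int))
    else:  # exact fit: dispersion is zero
        p_int = 0.0 if abs(intercept) > 1e-12 else 1.0
    return (
        MREstimate("egger", float(slope), se_slope, p_slope, j),
        EggerIntercept(float(intercept), se_int, p_int),
    )


def _weighted_median_core(ratio, weight):
    """Interpolated weighted median with centred cumulative weights."""
    order = np.argsort(ratio)
    r, w = ratio[order], weight[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5))
    # linear interpolation between the bracketing ratios
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(H: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
                    ) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Weights are inverse Wald-ratio variances (beta_x² / se_y², first order).
    The bootstrap redraws both effect vectors from normals at their
    observed values and SEs and recomputes the estimator; ``seed`` controls
    it and is required for reproducibility.
    """
    if H.n_snp < 3:
        raise InsufficientSnpsError("weighted median requires at least 3 SNPs")
    if seed is None:
        raise ValueError("seed is required")
    ratio, se_r, mask = wald_ratios(H)
    w = 1.0 / se_r**2
    est = _weighted_median_core(ratio, w)
    rng = np.random.default_rng(seed)
    bx, by = H.beta_x[mask], H.beta_y[mask]
    sx, sy = H.se_x[mask], H.se_y[mask]
    boots = np.empty(n_boot)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_star = rng.normal(by, sy, size=(n_boot, len(bx)))
    for b in range(n_boot):
        bxs = bx_star[b]
        ok = bxs != 0
        r = by_star[b, ok] / bxs[ok]
        boots[b] = _weighted_median_core(r, bxs[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", est, se, _normal_p(est, se), int(mask.sum()))


def _mode_core(ratio, weight, bandwidth_factor):
    """Peak of a normal-kernel weighted density over a ratio grid."""
    mad = np.median(np.abs(ratio - np.median(ratio)))
    s = 1.4826 * mad
    if s <= 0:
        return float(np.median(ratio))
    h = bandwidth_factor * 0.9 * s * len(ratio) ** (-1 / 5)
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 512)
    w = weight / weight.sum()
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2)).sum(0)
    return float(grid[int(np.argmax(dens))])


def mode_estimators(
    H: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[MREstimate, MREstimate]:
    """Simple-mode (unweighted) and weighted-mode causal estimates.

    The mode of the smoothed ratio density is consistent when the largest
    group of instruments with the same ratio is valid. Bandwidth follows a
    MAD-based normal-reference rule scaled by ``bandwidth_factor``; SEs come
    from the same parametric bootstrap as the weighted median.
    """
    if H.n_snp < 3:
        raise InsufficientSnpsError("mode estimators require at least 3 SNPs")
    if seed is None:
        raise ValueError("seed is required")
    ratio, se_r, mask = wald_ratios(H)
    w_inv = 1.0 / se_r**2
    ones = np.ones_like(ratio)
    est_s = _mode_core(ratio, ones, bandwidth_factor)
    est_w = _mode_core(ratio, w_inv, bandwidth_factor)
    rng = np.random.default_rng(seed)
    bx, by = H.beta_x[mask], H.beta_y[mask]
    sx, sy = H.se_x[mask], H.se_y[mask]
    boots = np.empty((n_boot, 2))
    bx_star = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_star = rng.normal(by, sy, size=(n_boot, len(bx)))
    for b in range(n_boot):
        bxs = bx_star[b]
        ok = bxs != 0
        r = by_star[b, ok] / bxs[ok]
        boots[b, 0] = _mode_core(r, np.ones(ok.sum()), bandwidth_factor)
        boots[b, 1] = _mode_core(r, bxs[ok] ** 2 / sy[ok] ** 2, bandwidth_factor)
    se_s = float(np.std(boots[:, 0], ddof=1))
    se_w = float(np.std(boots[:, 1], ddof=1))
    j = int(mask.sum())
    return (
        MREstimate("simple_mode", est_s, se_s, _normal_p(est_s, se_s), j),
        MREstimate("weighted_mode", est_w, se_w, _normal_p(est_w, se_w), j),
    )
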