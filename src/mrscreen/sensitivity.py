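"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

These diagnostics back the screen's second and third causal criteria:
"no heterogeneity or horizontal pleiotropy" is operationalized as
Cochran's Q p >= 0.05 AND MR-PRESSO global p >= 0.05 AND Egger intercept
p >= 0.05; "no single-SNP dominance" as leave-one-out stability (every
leave-one-out IVW estimate keeps the full estimate's sign and, when the
full estimate is significant, stays nominally significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCorrectionError,
    InsufficientSnpsError,
)
from .estimators import MREstimate, _ivw_fit, _normal_p, mr_egger, wald_ratios
from .harmonize import HarmonizedSet


@dataclass
class PressoResult:
    global_pval: float
    global_p_at_floor: bool
    outliers: list[str]
    distortion_pval: float | None
    corrected_estimate: MREstimate | None


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure–outcome analysis."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_pval: float | None = None
    radial_outliers: list[str] = field(default_factory=list)
    loo_estimates: list[MREstimate] = field(default_factory=list)
    loo_stable: bool = True

    @property
    def heterogeneity(self) -> bool:
        presso = self.presso_global_pval is not None and self.presso_global_pval < 0.05
        return self.q_pval < 0.05 or presso

    @property
    def pleiotropy(self) -> bool:
        return self.egger_intercept_pval < 0.05


def cochran_q(H: HarmonizedSet, beta_ref: float):
    """Cochran's Q of the Wald ratios about ``beta_ref``; chi-square p, J-1 df."""
    if H.n_snp < 2:
        raise InsufficientSnpsError("Cochran's Q requires at least 2 SNPs")
    ratio, se_r, _ = wald_ratios(H)
    q = float(np.sum((ratio - beta_ref) ** 2 / se_r**2))
    df = len(ratio) - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(H: HarmonizedSet):
    """(intercept, se, p): the pleiotropy component of the MR-Egger fit."""
    _, icpt = mr_egger(H)
    return icpt.estimate, icpt.se, icpt.pval


def radial_mr(H: HarmonizedSet, alpha: float = 0.05):
    """Radial reparameterization of the IVW fit exposing per-SNP Q terms.

    With first-order weights w_j = beta_x²/se_y², the radial slope equals
    the IVW slope and the per-SNP contributions Q_j = w_j (ratio_j - slope)²
    sum to Cochran's Q. SNPs whose Q_j exceeds the chi-square(1) quantile
    at ``alpha`` are flagged as outliers.
    """
    if H.n_snp < 2:
        raise InsufficientSnpsError("radial MR requires at least 2 SNPs")
    ratio, se_r, mask = wald_ratios(H)
    w = 1.0 / se_r**2
    slope = float(np.sum(w * ratio) / np.sum(w))
    q_per_snp = w * (ratio - slope) ** 2
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    snps = H.snp[mask]
    outliers = [str(s) for s, q in zip(snps, q_per_snp) if q > crit]
    return float(q_per_snp.sum()), q_per_snp, outliers


def _loo_slopes(bx, by, sy):
    """IVW slope excluding each SNP in turn, via sum subtraction."""
    w = 1.0 / sy**2
    num, den = np.sum(w * bx * by), np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def mr_presso(
    H: HarmonizedSet,
    n_sim: int = 10000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy, per-SNP outlier, and distortion tests.

    The observed residual sum of squares uses leave-one-out IVW predictions
    (each SNP's residual is judged against a slope it did not influence).
    The null distribution comes from ``n_sim`` parametric simulations
    redrawing both effect vectors; per-SNP empirical outlier p-values are
    Bonferroni-corrected across SNPs. Empirical p-values are floored at
    1/n_sim (``global_p_at_floor`` marks a "< floor" report).
    """
    j = H.n_snp
    if j < 4:
        raise InsufficientSnpsError("MR-PRESSO requires at least 4 SNPs")
    if seed is None:
        raise ValueError("seed is required")
    if n_sim < 100:
        raise ValueError("n_sim too small for empirical p-values")
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = H.beta_x, H.beta_y, H.se_x, H.se_y
    w = 1.0 / sy**2
    loo = _loo_slopes(bx, by, sy)
    d_obs = w * (by - loo * bx) ** 2
    rss_obs = float(d_obs.sum())

    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(loo * bx, sy, size=(n_sim, j))
    w_row = w[None, :]
    num = np.sum(w_row * bx_star * by_star, axis=1, keepdims=True)
    den = np.sum(w_row * bx_star**2, axis=1, keepdims=True)
    loo_star = (num - w_row * bx_star * by_star) / (den - w_row * bx_star**2)
    d_star = w_row * (by_star - loo_star * bx_star) ** 2
    rss_star = d_star.sum(axis=1)

    n_ge = int(np.sum(rss_star >= rss_obs))
    at_floor = n_ge == 0
    global_pval = max(n_ge, 1) / n_sim

    p_snp = np.maximum((d_star >= d_obs[None, :]).sum(axis=0), 1) / n_sim
    flagged = p_snp * j < alpha_outlier
    outliers = [str(s) for s in H.snp[flagged]]

    distortion_pval = None
    corrected = None
    if flagged.any():
        if flagged.all():
            raise DegenerateCorrectionError("every SNP flagged as an outlier")
        keep = ~flagged
        beta_all, _, _, _ = _ivw_fit(bx, by, sy)
        beta_free, se_free, _, _ = _ivw_fit(bx[keep], by[keep], sy[keep])
        d_obs_shift = abs(beta_all - beta_free)
        k = int(flagged.sum())
        n_dist = min(n_sim, 5000)
        shifts = np.empty(n_dist)
        idx = np.arange(j)
        for b in range(n_dist):
            drop = rng.choice(idx, size=k, replace=False)
            m = np.ones(j, dtype=bool)
            m[drop] = False
            beta_b, _, _, _ = _ivw_fit(bx[m], by[m], sy[m])
            shifts[b] = abs(beta_all - beta_b)
        distortion_pval = max(int(np.sum(shifts >= d_obs_shift)), 1) / n_dist
        corrected = MREstimate(
            "ivw_presso_corrected", beta_free, se_free,
            _normal_p(beta_free, se_free), int(keep.sum()),
        )
    return PressoResult(global_pval, at_floor, outliers, distortion_pval, corrected)


def leave_one_out(H: HarmonizedSet):
    """J IVW estimates each excluding one SNP, plus a stability verdict.

    Stable means every leave-one-out estimate keeps the full estimate's
    sign, and stays nominally significant (p < 0.05) whenever the full
    estimate is significant.
    """
    if H.n_snp < 3:
        raise InsufficientSnpsError("leave-one-out requires at least 3 SNPs")
    full_beta, full_se, _, _ = _ivw_fit(H.beta_x, H.beta_y, H.se_y)
    full_p = _normal_p(full_beta, full_se)
    estimates = []
    stable = True
    for jj in range(H.n_snp):
        sub = H.drop([jj])
        beta, se, _, _ = _ivw_fit(sub.beta_x, sub.beta_y, sub.se_y)
        p = _normal_p(beta, se)
        estimates.append(MREstimate("ivw_loo", beta, se, p, sub.n_snp))
        if np.sign(beta) != np.sign(full_beta) and full_beta != 0:
            stable = False
        if full_p < 0.05 and p >= 0.05:
            stable = False
    return estimates, stable


def run_sensitivity(
    H: HarmonizedSet,
    beta_ivw: float,
    seed: int,
    presso_nsim: int = 10000,
    presso_alpha_outlier: float = 0.05,
    radial_alpha: float = 0.05,
) -> SensitivityReport:
    """Assemble the full sensitivity report for one analysis."""
    q, q_df, q_p = cochran_q(H, beta_ivw)
    icpt, icpt_se, icpt_p = egger_intercept_test(H)
    _, _, radial_out = radial_mr(H, radial_alpha)
    report = SensitivityReport(
        q_stat=q, q_df=q_df, q_pval=q_p,
        egger_intercept=icpt, egger_intercept_se=icpt_se,
        egger_intercept_pval=icpt_p,
        radial_outliers=radial_out,
    )
    if H.n_snp >= 4:
        presso = mr_presso(H, n_sim=presso_nsim, seed=seed,
                           alpha_outlier=presso_alpha_outlier)
        report.presso_global_pval = presso.global_pval
        report.presso_outliers = presso.outliers
        report.presso_distortion_pval = presso.distortion_pval
    report.loo_estimates, report.loo_stable = leave_one_out(H)
    return report
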