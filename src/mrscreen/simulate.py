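"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure the screen assumes: a
metabolite GWAS (continuous trait, ~7800 subjects) supplying instrument
effects, and a much larger disease GWAS (log-odds scale) whose per-SNP
effects follow a known causal slope theta plus optional pleiotropy and
planted outliers:

    beta_x_j = gamma_j + e_xj,   gamma_j ~ N(0, gamma_sd²), e_xj ~ N(0, se_x²)
    beta_y_j = theta·gamma_j + alpha_j + e_yj,  e_yj ~ N(0, se_y²)

Pleiotropy alpha_j is N(pleio_mean, pleio_sd²) (balanced when the mean is
0, directional otherwise); a deterministic-under-seed subset of size
round(outlier_frac·J) instead receives ±outlier_scale·se_y. Background
SNPs are drawn under the null so the significance filter and clumping
have realistic work to do, and a configurable fraction of SNPs carries
palindromic or incompatible alleles to exercise harmonization. LD-score /
chi-square pairs for the LDSC stage follow the linear polygenic model
exactly, with LD scores from a shifted gamma (min 1).

Default scales mirror the study design this emulates: instrument effects
with gamma_sd = 0.1 and se_x = 0.01 (strong instruments, F ~ 100, as
metabolite GWAS instruments passing p < 1e-5 typically are), disease
se_y = 0.03 (log-odds SEs for ~7.3k cases / 358k controls), exposure
n = 7824 and outcome n = 365,120.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .harmonize import HarmonizedSet, from_arrays
from .ldsc import LdscInput
from .sumstats import SummaryDataset, TraitMeta

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic exposure–outcome pair."""

    seed: int
    n_snp_instrument: int = 30
    background_per_instrument: int = 50
    theta: float = 0.0
    gamma_sd: float = 0.1
    se_x: float = 0.01
    se_y: float = 0.03
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0
    palindrome_frac: float = 0.1
    mismatch_frac: float = 0.02
    swap_frac: float = 0.2  # outcome rows reported on the opposite allele
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_exposure: int = 7824
    n_outcome: int = 365_120
    oriented_instruments: bool = False  # gamma_j >= 0 (Egger-style simulations)
    select_significant: bool = False  # condition instruments on p_x < sig_threshold
    sig_threshold: float = 1e-5
    correlated_pleiotropy: float = 0.0  # corr(alpha, gamma); 0 keeps InSIDE
    h2_true: float = 0.3
    rg_true: float = 0.0
    m_total: int = 5000
    ell_shape: float = 3.0
    ell_scale: float = 10.0
    n_ldsc: int = 20_000

    def __post_init__(self) -> None:
        for name in ("outlier_frac", "palindrome_frac", "mismatch_frac", "swap_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0,1]")
        for name in ("gamma_sd", "se_x", "se_y", "pleio_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not (0 <= self.h2_true <= 1) or abs(self.rg_true) > 1:
            raise ConfigError("h2_true in [0,1], |rg_true| <= 1 required")


@dataclass
class Truth:
    """Ground truth backing one simulated pair."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    noise_x: np.ndarray
    noise_y: np.ndarray
    outlier_snps: list[str]
    instrument_snps: list[str]


def _effects(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw instrument-level true and observed effects (vectorized)."""
    j = cfg.n_snp_instrument
    gamma = rng.normal(0.0, cfg.gamma_sd, j)
    if cfg.oriented_instruments:
        gamma = np.abs(gamma)
    alpha = rng.normal(cfg.pleio_mean, cfg.pleio_sd, j) if cfg.pleio_sd or cfg.pleio_mean \
        else np.zeros(j)
    if cfg.correlated_pleiotropy and cfg.pleio_sd:
        alpha = cfg.correlated_pleiotropy * cfg.pleio_sd / cfg.gamma_sd * gamma + \
            np.sqrt(1 - cfg.correlated_pleiotropy**2) * (alpha - cfg.pleio_mean) + cfg.pleio_mean
    n_out = int(round(cfg.outlier_frac * j))
    outlier_idx = rng.permutation(j)[:n_out]
    signs = rng.choice([-1.0, 1.0], size=n_out)
    alpha[outlier_idx] = signs * cfg.outlier_scale * cfg.se_y
    ex = rng.normal(0.0, cfg.se_x, j)
    ey = rng.normal(0.0, cfg.se_y, j)
    bx = gamma + ex
    if cfg.select_significant:
        # emulate the instrument significance filter: redraw (gamma, e_x)
        # until every observed effect passes the exposure p-threshold
        z_crit = stats.norm.isf(cfg.sig_threshold / 2.0)
        for _ in range(10_000):
            weak = np.abs(bx) < z_crit * cfg.se_x
            if not weak.any():
                break
            nw = int(weak.sum())
            g_new = rng.normal(0.0, cfg.gamma_sd, nw)
            if cfg.oriented_instruments:
                g_new = np.abs(g_new)
            gamma[weak] = g_new
            ex[weak] = rng.normal(0.0, cfg.se_x, nw)
            bx[weak] = gamma[weak] + ex[weak]
        else:
            raise ConfigError("instrument strength too weak for sig_threshold")
    by = cfg.theta * gamma + alpha + ey
    return gamma, alpha, ex, ey, bx, by, outlier_idx


def simulate_harmonized(cfg: SimulationConfig) -> tuple[HarmonizedSet, Truth]:
    """Directly emit an aligned effect set (fast path for estimator studies).

    Skips alleles/filtering: the instruments are already selected and
    harmonized, which is the frame in which the estimators and diagnostics
    are defined.
    """
    rng = np.random.default_rng(cfg.seed)
    gamma, alpha, ex, ey, bx, by, out_idx = _effects(cfg, rng)
    j = cfg.n_snp_instrument
    snps = np.array([f"rs{100 + i}" for i in range(j)])
    H = from_arrays(bx, np.full(j, cfg.se_x), by, np.full(j, cfg.se_y), snp=snps)
    truth = Truth(cfg.theta, gamma, alpha, ex, ey,
                  [str(s) for s in snps[out_idx]], list(map(str, snps)))
    return H, truth


def _alleles(rng, n, palindrome_frac):
    pal = rng.random(n) < palindrome_frac
    choice_np = rng.integers(0, len(_NONPALINDROMIC), n)
    choice_p = rng.integers(0, len(_PALINDROMIC), n)
    ea, oa = [], []
    for i in range(n):
        a, b = _PALINDROMIC[choice_p[i]] if pal[i] else _NONPALINDROMIC[choice_np[i]]
        ea.append(a)
        oa.append(b)
    return np.array(ea), np.array(oa), pal


def simulate_pair(cfg: SimulationConfig) -> tuple[SummaryDataset, SummaryDataset, Truth]:
    """Full synthetic exposure and outcome summary datasets plus ground truth.

    Instruments are spaced >= 1 Mb apart across chromosomes so clumping
    retains them; background SNPs are packed near instruments and drawn
    under the null. Palindromic instruments draw their frequency inside
    [0.40, 0.60] half the time so both palindrome branches are exercised;
    a ``swap_frac`` fraction of outcome rows is reported on the opposite
    allele (negated beta, complemented frequency) to exercise flipping.
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snp_instrument
    n_bg = cfg.background_per_instrument * j
    n_all = j + n_bg
    gamma, alpha, ex, ey, bx_inst, by_inst, out_idx = _effects(cfg, rng)

    snps = np.array([f"rs{i + 1}" for i in range(n_all)])
    inst = np.zeros(n_all, dtype=bool)
    inst[:j] = True
    chrom = np.empty(n_all, dtype=object)
    pos = np.empty(n_all)
    chrom[:j] = [str(1 + i % 22) for i in range(j)]
    pos[:j] = [10_000_000 + 2_000_000 * (i // 22) for i in range(j)]
    chrom[j:] = [str(1 + i % 22) for i in range(n_bg)]
    pos[j:] = 200_000_000 + 1_000 * np.arange(n_bg)  # far from instruments

    ea, oa, pal = _alleles(rng, n_all, cfg.palindrome_frac)
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, n_all)
    eaf = np.where(rng.random(n_all) < 0.5, maf, 1 - maf)
    mid = rng.random(n_all) < 0.5  # palindromes: ambiguous band half the time
    eaf = np.where(pal & mid, rng.uniform(0.40, 0.60, n_all), eaf)
    eaf = np.where(pal & ~mid, np.where(eaf < 0.5, rng.uniform(cfg.maf_low, 0.39, n_all),
                                        rng.uniform(0.61, 1 - cfg.maf_low, n_all)), eaf)

    beta_x = np.empty(n_all)
    beta_x[:j] = bx_inst
    beta_x[j:] = rng.normal(0.0, cfg.se_x, n_bg)
    se_x = np.full(n_all, cfg.se_x)
    beta_y = np.empty(n_all)
    beta_y[:j] = by_inst
    beta_y[j:] = rng.normal(0.0, cfg.se_y, n_bg)
    se_y = np.full(n_all, cfg.se_y)

    def _dataset(beta, se, n, meta):
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        return pd.DataFrame({
            "snp": snps, "chrom": chrom, "pos": pos.astype(int),
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": beta, "se": se, "pval": p, "n": float(n),
        }), meta

    exp_df, exp_meta = _dataset(beta_x, se_x, cfg.n_exposure,
                                TraitMeta("synthetic_metabolite", "synthetic metabolite"))
    out_df, out_meta = _dataset(beta_y, se_y, cfg.n_outcome,
                                TraitMeta("synthetic_disease", "synthetic disease",
                                          "binary", cfg.n_outcome, 7306))

    # report some outcome rows on the opposite allele frame
    swap = rng.random(n_all) < cfg.swap_frac
    out_df.loc[swap, ["effect_allele", "other_allele"]] = \
        out_df.loc[swap, ["other_allele", "effect_allele"]].to_numpy()
    out_df.loc[swap, "beta"] = -out_df.loc[swap, "beta"]
    out_df.loc[swap, "eaf"] = 1.0 - out_df.loc[swap, "eaf"]

    # incompatible allele pairs between the two sources
    mism = (rng.random(n_all) < cfg.mismatch_frac) & ~pal & ~swap
    flip_other = {"G": "C", "C": "G", "A": "T", "T": "A"}
    out_df.loc[mism, "other_allele"] = [
        flip_other[a] if flip_other[a] != e else ("G" if e != "G" else "C")
        for e, a in zip(out_df.loc[mism, "effect_allele"], out_df.loc[mism, "other_allele"])
    ]

    truth = Truth(cfg.theta, gamma, alpha, ex, ey,
                  [str(s) for s in snps[:j][out_idx]], list(map(str, snps[:j])))
    return (SummaryDataset(exp_meta, exp_df), SummaryDataset(out_meta, out_df), truth)


@dataclass
class LdscTruth:
    h2_1: float
    h2_2: float
    rg: float


def simulate_ldsc_inputs(cfg: SimulationConfig) -> tuple[LdscInput, LdscInput, LdscTruth]:
    """LD-score / z-statistic pairs obeying the LDSC regression model.

    ell_j ~ 1 + Gamma(shape, scale); (z1_j, z2_j) are jointly normal with
    Var(z_i) = 1 + n h2_i ell_j / M and Cov = rg sqrt(n1 n2 h2_1 h2_2) ell_j / M
    (no sample-overlap term).
    """
    rng = np.random.default_rng(cfg.seed)
    m_obs = cfg.m_total  # all M SNPs observed at desk scale
    ell = 1.0 + rng.gamma(cfg.ell_shape, cfg.ell_scale, m_obs)
    n = float(cfg.n_ldsc)
    v1 = 1.0 + n * cfg.h2_true * ell / cfg.m_total
    v2 = v1.copy()
    cov = cfg.rg_true * n * cfg.h2_true * ell / cfg.m_total
    # bivariate normal via conditional draw
    z1 = rng.normal(0.0, np.sqrt(v1))
    cond_mean = cov / v1 * z1
    cond_var = v2 - cov**2 / v1
    z2 = rng.normal(cond_mean, np.sqrt(cond_var))
    snps = np.array([f"rs{i + 1}" for i in range(m_obs)])
    narr = np.full(m_obs, n)
    inp1 = LdscInput(snps, z1, ell, narr, cfg.m_total)
    inp2 = LdscInput(snps, z2, ell, narr, cfg.m_total)
    return inp1, inp2, LdscTruth(cfg.h2_true, cfg.h2_true, cfg.rg_true)


def simulate_metabolite_panel(
    cfg: SimulationConfig,
    n_metabolites: int,
    effect_metabolites: int,
    effect_theta: float = 0.5,
) -> tuple[list[SummaryDataset], SummaryDataset, dict[str, float]]:
    """A screen-scale panel: several metabolites sharing one outcome.

    The first ``effect_metabolites`` get causal slope ``effect_theta``; the
    rest are null. Each metabolite has its own instruments; the outcome
    dataset is the union of all outcome rows. Returns the exposures, the
    pooled outcome and a {metabolite_id: true_theta} map.
    """
    rng = np.random.default_rng(cfg.seed)
    exposures, out_frames = [], []
    truth_map: dict[str, float] = {}
    for i in range(n_metabolites):
        theta = effect_theta if i < effect_metabolites else 0.0
        sub = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)), theta=theta)
        exp, out, _ = simulate_pair(sub)
        mid = f"met{i:03d}"
        exp.meta = TraitMeta(mid, mid, "quantitative", cfg.n_exposure)
        exp.table = exp.table.assign(snp=[f"{mid}_{s}" for s in exp.table["snp"]])
        out.table = out.table.assign(snp=[f"{mid}_{s}" for s in out.table["snp"]])
        exposures.append(exp)
        out_frames.append(out.table)
        truth_map[mid] = theta
    outcome_meta = TraitMeta("synthetic_disease", "synthetic disease",
                             "binary", cfg.n_outcome, 7306)
    outcome = SummaryDataset(outcome_meta,
                             pd.concat(out_frames, ignore_index=True))
    return exposures, outcome, truth_map
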