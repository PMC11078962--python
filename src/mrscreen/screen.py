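"""Forward/reverse MR screen over a metabolite panel with the decision rule.

A metabolite's causal claim must clear three criteria in order:

1. significant primary IVW estimate (p < 0.05);
2. no detectable heterogeneity (Cochran's Q and MR-PRESSO global, both
   p >= 0.05) and no directional pleiotropy (Egger intercept p >= 0.05);
3. leave-one-out stability (no single SNP drives the estimate);

and additionally must not show pleiotropic reverse-direction instruments
(reverse MR with disease as exposure). The first failed gate names the
verdict. Raw p-values are used across the panel — no multiple-testing
correction is applied by default, which the run manifest states
explicitly; a Benjamini–Hochberg column is emitted for users who want it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyHarmonizationError, MrScreenError
from .estimators import MREstimate, ivw_mre, mode_estimators, mr_egger, weighted_median
from .harmonize import HarmonizedSet, harmonize
from .instruments import ClumpConfig, InsufficientInstruments, select_instruments
from .ldsc import (
    LdscResult,
    RgResult,
    estimate_h2,
    estimate_rg,
    ldsc_input_from_sumstats,
)
from .sensitivity import SensitivityReport, run_sensitivity
from .sumstats import SummaryDataset

VERDICTS = (
    "validated", "failed_c1", "failed_c2", "failed_c3",
    "excluded_reverse_pleiotropy", "insufficient_ivs",
)


@dataclass
class ScreenConfig:
    """All knobs of the screen, with the study's defaults."""

    seed: int = 0
    p_threshold: float = 1e-5
    r2_max: float = 0.01
    window_bp: int = 500_000
    f_min: float = 10.0
    min_ivs: int = 4
    maf_band_low: float = 0.40
    maf_band_high: float = 0.60
    strict_palindromes: bool = False
    n_boot: int = 1000
    presso_nsim: int = 10_000
    presso_alpha_outlier: float = 0.05
    radial_alpha: float = 0.05
    alpha: float = 0.05
    mode: str = "staged"  # WM/Egger only for IVW-significant; "full" = always
    ldsc_all: bool = False
    reverse: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("staged", "full"):
            raise ConfigError("mode must be 'staged' or 'full'")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0,1)")

    def clump_config(self, ld_source=None) -> ClumpConfig:
        return ClumpConfig(self.p_threshold, self.r2_max, self.window_bp, ld_source)


@dataclass
class DecisionRecord:
    """Per-metabolite verdict with all contributing results."""

    metabolite_id: str
    verdict: str
    n_iv: int = 0
    ivw: MREstimate | None = None
    wm: MREstimate | None = None
    egger: MREstimate | None = None
    simple_mode: MREstimate | None = None
    weighted_mode: MREstimate | None = None
    sens: SensitivityReport | None = None
    criterion1: bool | None = None
    criterion2: bool | None = None
    criterion3: bool | None = None
    reverse_significant: bool | None = None
    reverse_pleiotropic: bool | None = None
    ldsc_h2: LdscResult | None = None
    ldsc_rg: RgResult | None = None


def apply_decision_rule(
    metabolite_id: str,
    n_iv: int,
    ivw: MREstimate,
    sens: SensitivityReport | None,
    reverse_pleiotropic: bool | None,
    alpha: float = 0.05,
    **extra,
) -> DecisionRecord:
    """Evaluate the gates in order c1 → c2 → c3 → reverse exclusion."""
    c1 = ivw.pval < alpha
    if not c1:
        return DecisionRecord(metabolite_id, "failed_c1", n_iv, ivw=ivw,
                              criterion1=False, **extra)
    c2 = sens is not None and not sens.heterogeneity and not sens.pleiotropy
    if not c2:
        return DecisionRecord(metabolite_id, "failed_c2", n_iv, ivw=ivw, sens=sens,
                              criterion1=True, criterion2=False, **extra)
    c3 = sens.loo_stable
    if not c3:
        return DecisionRecord(metabolite_id, "failed_c3", n_iv, ivw=ivw, sens=sens,
                              criterion1=True, criterion2=True, criterion3=False,
                              **extra)
    if reverse_pleiotropic:
        return DecisionRecord(metabolite_id, "excluded_reverse_pleiotropy", n_iv,
                              ivw=ivw, sens=sens, criterion1=True, criterion2=True,
                              criterion3=True, reverse_pleiotropic=True, **extra)
    return DecisionRecord(metabolite_id, "validated", n_iv, ivw=ivw, sens=sens,
                          criterion1=True, criterion2=True, criterion3=True,
                          reverse_pleiotropic=bool(reverse_pleiotropic is not None and
                                                   reverse_pleiotropic), **extra)


def _analyze_one(
    H: HarmonizedSet, config: ScreenConfig, seed: int, full: bool
):
    """IVW, follow-up estimators and sensitivity for one harmonized set."""
    ivw = ivw_mre(H)
    significant = ivw.pval < config.alpha
    wm = egger_est = smode = wmode = None
    sens = None
    if significant or full:
        egger_est, _ = mr_egger(H)
        wm = weighted_median(H, n_boot=config.n_boot, seed=seed)
        smode, wmode = mode_estimators(H, seed=seed + 1, n_boot=config.n_boot)
        sens = run_sensitivity(
            H, ivw.beta, seed=seed + 2, presso_nsim=config.presso_nsim,
            presso_alpha_outlier=config.presso_alpha_outlier,
            radial_alpha=config.radial_alpha,
        )
    return ivw, wm, egger_est, smode, wmode, sens


def run_reverse_mr(
    outcome_as_exposure: SummaryDataset,
    metabolite: SummaryDataset,
    config: ScreenConfig,
    ld_source=None,
    seed: int | None = None,
):
    """Reverse-direction MR: disease instruments against one metabolite.

    Returns (MREstimate or None, SensitivityReport or None,
    reverse_significant, reverse_pleiotropic). Missing results (too few
    disease instruments, empty harmonization) yield (None, None, False, False):
    with no usable reverse instruments no reverse signal can be claimed.
    """
    seed = config.seed if seed is None else seed
    sel = select_instruments(
        outcome_as_exposure, metabolite, config.clump_config(ld_source),
        f_min=config.f_min, min_ivs=max(2, config.min_ivs),
    )
    if isinstance(sel, InsufficientInstruments):
        return None, None, False, False
    try:
        H = harmonize(sel, metabolite,
                      (config.maf_band_low, config.maf_band_high),
                      config.strict_palindromes)
    except EmptyHarmonizationError:
        return None, None, False, False
    if H.n_snp < 2:
        return None, None, False, False
    ivw = ivw_mre(H)
    sens = None
    pleiotropic = False
    if H.n_snp >= 3:
        sens = run_sensitivity(
            H, ivw.beta, seed=seed, presso_nsim=config.presso_nsim,
            presso_alpha_outlier=config.presso_alpha_outlier,
            radial_alpha=config.radial_alpha,
        )
        pleiotropic = sens.pleiotropy
    return ivw, sens, ivw.pval < config.alpha, pleiotropic


def run_forward_screen(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    config: ScreenConfig,
    ld_source=None,
    outcome_as_exposure: SummaryDataset | None = None,
    ld_scores: pd.DataFrame | None = None,
) -> tuple[list[DecisionRecord], dict]:
    """Screen every metabolite against the outcome.

    Per metabolite: instrument selection → harmonization → IVW → (for
    IVW-significant metabolites, or all in "full" mode) WM/Egger/modes and
    the sensitivity battery → decision rule. Reverse MR runs for
    metabolites clearing criteria 1–3 when ``outcome_as_exposure`` is
    given; LDSC heritability and genetic correlation annotate validated
    metabolites (all, with ``config.ldsc_all``) when an (snp, l2) table is
    given. Returns the records and a run log of per-stage counts.
    """
    records: list[DecisionRecord] = []
    log = {"n_exposures": len(exposures), "insufficient_ivs": 0,
           "analyzed": 0, "ivw_significant": 0, "reverse_runs": 0}
    full = config.mode == "full"
    base_seed = int(config.seed)
    for k, exposure in enumerate(exposures):
        mid = exposure.meta.trait_id
        seed = base_seed + 1000 * (k + 1)
        sel = select_instruments(exposure, outcome, config.clump_config(ld_source),
                                 f_min=config.f_min, min_ivs=config.min_ivs)
        if isinstance(sel, InsufficientInstruments):
            log["insufficient_ivs"] += 1
            records.append(DecisionRecord(mid, "insufficient_ivs", sel.count))
            continue
        try:
            H = harmonize(sel, outcome,
                          (config.maf_band_low, config.maf_band_high),
                          config.strict_palindromes)
        except EmptyHarmonizationError:
            log["insufficient_ivs"] += 1
            records.append(DecisionRecord(mid, "insufficient_ivs", 0))
            continue
        if H.n_snp < config.min_ivs:
            log["insufficient_ivs"] += 1
            records.append(DecisionRecord(mid, "insufficient_ivs", H.n_snp))
            continue
        log["analyzed"] += 1
        ivw, wm, egger_est, smode, wmode, sens = _analyze_one(H, config, seed, full)
        if ivw.pval < config.alpha:
            log["ivw_significant"] += 1
        rev_sig = rev_pleio = None
        passes_c123 = (
            ivw.pval < config.alpha and sens is not None
            and not sens.heterogeneity and not sens.pleiotropy and sens.loo_stable
        )
        if config.reverse and outcome_as_exposure is not None and passes_c123:
            log["reverse_runs"] += 1
            _, _, rev_sig, rev_pleio = run_reverse_mr(
                outcome_as_exposure, exposure, config, ld_source, seed=seed + 3)
        record = apply_decision_rule(
            mid, H.n_snp, ivw, sens, rev_pleio, config.alpha,
            wm=wm, egger=egger_est, simple_mode=smode, weighted_mode=wmode,
            reverse_significant=rev_sig,
        )
        if ld_scores is not None and (config.ldsc_all or record.verdict == "validated"):
            try:
                inp_x = ldsc_input_from_sumstats(exposure, ld_scores)
                record.ldsc_h2 = estimate_h2(inp_x)
                inp_y = ldsc_input_from_sumstats(outcome, ld_scores)
                record.ldsc_rg = estimate_rg(inp_x, inp_y)
            except MrScreenError:
                pass  # too little overlap: annotations stay absent
        records.append(record)
    log["verdicts"] = {v: sum(r.verdict == v for r in records) for v in VERDICTS}
    return records, log


def _fmt(x, reliable=True):
    return "NA" if x is None or not reliable or (isinstance(x, float) and not np.isfinite(x)) else x


def estimates_frame(records: list[DecisionRecord]) -> pd.DataFrame:
    """One row per metabolite × method with beta/OR/CI/p."""
    rows = []
    for r in records:
        for est in (r.ivw, r.egger, r.wm, r.simple_mode, r.weighted_mode):
            if est is None:
                continue
            rows.append({
                "metabolite": r.metabolite_id, "method": est.method,
                "n_snp": est.n_snp, "beta": est.beta, "se": est.se,
                "or": est.or_, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "pval": est.pval,
            })
    return pd.DataFrame(rows)


def decisions_frame(records: list[DecisionRecord]) -> pd.DataFrame:
    """One row per metabolite: criteria, verdict, LDSC annotations, BH-FDR."""
    rows = []
    for r in records:
        rows.append({
            "metabolite": r.metabolite_id, "verdict": r.verdict, "n_iv": r.n_iv,
            "ivw_beta": _fmt(r.ivw.beta if r.ivw else None),
            "ivw_or": _fmt(r.ivw.or_ if r.ivw else None),
            "ivw_pval": _fmt(r.ivw.pval if r.ivw else None),
            "criterion1": _fmt(r.criterion1), "criterion2": _fmt(r.criterion2),
            "criterion3": _fmt(r.criterion3),
            "reverse_significant": _fmt(r.reverse_significant),
            "reverse_pleiotropic": _fmt(r.reverse_pleiotropic),
            "h2": _fmt(r.ldsc_h2.h2 if r.ldsc_h2 else None,
                       r.ldsc_h2.reliable if r.ldsc_h2 else True),
            "h2_pval": _fmt(r.ldsc_h2.h2_pval if r.ldsc_h2 else None,
                            r.ldsc_h2.reliable if r.ldsc_h2 else True),
            "rg": _fmt(r.ldsc_rg.rg if r.ldsc_rg else None,
                       r.ldsc_rg.reliable if r.ldsc_rg else True),
            "rg_pval": _fmt(r.ldsc_rg.rg_pval if r.ldsc_rg else None,
                            r.ldsc_rg.reliable if r.ldsc_rg else True),
        })
    df = pd.DataFrame(rows)
    pvals = pd.to_numeric(df["ivw_pval"], errors="coerce")
    df["ivw_fdr_bh"] = _bh_fdr(pvals.to_numpy(float))
    return df


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-aware)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    n = len(pv)
    if n == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def sensitivity_frame(records: list[DecisionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        s = r.sens
        if s is None:
            continue
        rows.append({
            "metabolite": r.metabolite_id, "q_stat": s.q_stat, "q_df": s.q_df,
            "q_pval": s.q_pval, "egger_intercept": s.egger_intercept,
            "egger_intercept_se": s.egger_intercept_se,
            "egger_intercept_pval": s.egger_intercept_pval,
            "presso_global_pval": _fmt(s.presso_global_pval),
            "presso_outliers": ";".join(s.presso_outliers) or "none",
            "presso_distortion_pval": _fmt(s.presso_distortion_pval),
            "radial_outliers": ";".join(s.radial_outliers) or "none",
            "loo_stable": s.loo_stable,
        })
    return pd.DataFrame(rows)


def run_manifest(config: ScreenConfig, log: dict) -> str:
    """Machine-readable record of run parameters and stage counts."""
    payload = {
        "config": {k: getattr(config, k) for k in (
            "seed", "p_threshold", "r2_max", "window_bp", "f_min", "min_ivs",
            "maf_band_low", "maf_band_high", "strict_palindromes", "n_boot",
            "presso_nsim", "alpha", "mode", "reverse")},
        "multiple_testing": "criterion1 uses raw p < alpha (no FDR); "
                            "ivw_fdr_bh column provided for reference",
        "log": log,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
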