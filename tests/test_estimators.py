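import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.errors import DegenerateInputError, InsufficientSnpsError
from mrscreen.estimators import (
    ivw_mre,
    ivw_single,
    mode_estimators,
    mr_egger,
    wald_ratios,
    weighted_median,
)
from mrscreen.harmonize import from_arrays
from mrscreen.simulate import SimulationConfig, simulate_harmonized


# ---------- independent oracles ----------

def wls_oracle(bx, by, w, intercept):
    """Weighted least squares by explicit design-matrix lstsq (oracle path)."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(bx), bx]) if intercept else bx[:, None]
    coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
    return coef


def wm_oracle(ratio, w):
    """Weighted median by explicit cumulative-weight interpolation."""
    order = np.argsort(ratio)
    r, ww = np.asarray(ratio)[order], np.asarray(w)[order]
    ww = ww / ww.sum()
    s = np.cumsum(ww) - ww / 2
    return float(np.interp(0.5, s, r))


# ---------- Wald ratios ----------

class TestWald:
    def test_direct_evaluation(self):
        H = from_arrays([0.1], [0.01], [0.05], [0.01])
        ratio, se, _ = wald_ratios(H)
        assert ratio[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.1)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        H = from_arrays([0.1], [0.01], [0.0], [0.01])
        assert wald_ratios(H)[0][0] == 0.0

    def test_exposure_sign_flip_flips_ratio(self):
        H1 = from_arrays([0.1], [0.01], [0.05], [0.01])
        H2 = from_arrays([-0.1], [0.01], [0.05], [0.01])
        assert wald_ratios(H1)[0][0] == -wald_ratios(H2)[0][0]

    def test_all_zero_exposure_degenerate(self):
        H = from_arrays([0.0, 0.0], [0.01, 0.01], [0.1, 0.1], [0.01, 0.01])
        with pytest.raises(DegenerateInputError):
            wald_ratios(H)

    def test_second_order_se_exceeds_first(self):
        H = from_arrays([0.1], [0.05], [0.05], [0.01])
        _, se1, _ = wald_ratios(H, "first")
        _, se2, _ = wald_ratios(H, "second")
        assert se2[0] > se1[0]


# ---------- IVW ----------

class TestIVW:
    def test_consensus_ratio_recovered_with_unit_dispersion(self):
        bx = np.array([0.1, 0.2, 0.05, 0.15])
        r = 0.7
        H = from_arrays(bx, 0.01 * np.ones(4), r * bx, [0.02, 0.01, 0.03, 0.02])
        est = ivw_mre(H)
        assert est.beta == pytest.approx(r)
        # Q = 0 so the overdispersion floor applies: se = fixed-effect se
        w = 1 / np.array([0.02, 0.01, 0.03, 0.02]) ** 2
        assert est.se == pytest.approx(np.sqrt(1 / np.sum(w * bx**2)))

    def test_matches_normal_equations_oracle(self, fixed_harmonized):
        H = fixed_harmonized
        est = ivw_mre(H)
        w = 1 / H.se_y**2
        oracle = wls_oracle(H.beta_x, H.beta_y, w, intercept=False)[0]
        assert est.beta == pytest.approx(oracle, rel=1e-10)

    def test_single_snp_path_equals_wald_ratio(self):
        H = from_arrays([0.1], [0.01], [0.05], [0.02])
        est = ivw_single(H)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        with pytest.raises(InsufficientSnpsError):
            ivw_mre(H)

    def test_or_ci_consistency(self, fixed_harmonized):
        est = ivw_mre(fixed_harmonized)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low < est.or_ < est.ci_high
        assert est.ci_low == pytest.approx(np.exp(est.beta - 1.959964 * est.se), rel=1e-5)


# ---------- MR-Egger ----------

class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        a, b = 0.02, 0.6
        H = from_arrays(bx, 0.01 * np.ones(5), a + b * bx, 0.02 * np.ones(5))
        slope, icpt = mr_egger(H)
        assert slope.beta == pytest.approx(b, abs=1e-12)
        assert icpt.estimate == pytest.approx(a, abs=1e-12)

    def test_matches_normal_equations_oracle(self, fixed_harmonized):
        H = fixed_harmonized
        slope, icpt = mr_egger(H)
        sign = np.where(H.beta_x < 0, -1.0, 1.0)
        coef = wls_oracle(sign * H.beta_x, sign * H.beta_y, 1 / H.se_y**2, True)
        assert icpt.estimate == pytest.approx(coef[0], rel=1e-10)
        assert slope.beta == pytest.approx(coef[1], rel=1e-10)

    def test_too_few_snps(self):
        H = from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientSnpsError):
            mr_egger(H)

    def test_directional_pleiotropy_mean_recovered(self, rep_seeds):
        icpts = []
        for s in rep_seeds("eggrec", 400):
            H, _ = simulate_harmonized(SimulationConfig(
                seed=int(s), theta=0.2, pleio_mean=0.05, pleio_sd=0.01,
                oriented_instruments=True, select_significant=True))
            icpts.append(mr_egger(H)[1].estimate)
        mc_se = np.std(icpts) / np.sqrt(len(icpts))
        assert np.mean(icpts) == pytest.approx(0.05, abs=4 * mc_se + 1e-3)


# ---------- weighted median ----------

class TestWeightedMedian:
    def test_odd_j_equal_weights_is_middle_ratio(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.03, 0.05, 0.09])
        H = from_arrays(bx, [0.01] * 3, by, [0.02] * 3)
        est = weighted_median(H, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_matches_cumulative_weight_oracle(self):
        bx = np.array([0.12, 0.2, 0.09, 0.3])
        by = np.array([0.05, 0.15, 0.02, 0.12])
        sy = np.array([0.02, 0.03, 0.025, 0.02])
        H = from_arrays(bx, 0.01 * np.ones(4), by, sy)
        est = weighted_median(H, n_boot=100, seed=2)
        oracle = wm_oracle(by / bx, bx**2 / sy**2)
        assert est.beta == pytest.approx(oracle, rel=1e-10)

    def test_seed_reproducible(self, fixed_harmonized):
        a = weighted_median(fixed_harmonized, n_boot=200, seed=7)
        b = weighted_median(fixed_harmonized, n_boot=200, seed=7)
        assert a.se == b.se

    def test_seed_required(self, fixed_harmonized):
        with pytest.raises(ValueError):
            weighted_median(fixed_harmonized, n_boot=100)


# ---------- mode estimators ----------

class TestModes:
    def test_consensus_ratio(self):
        bx = np.array([0.1, 0.2, 0.15])
        H = from_arrays(bx, [0.01] * 3, 0.4 * bx, [0.02] * 3)
        s, w = mode_estimators(H, n_boot=50, seed=1)
        assert s.beta == pytest.approx(0.4)
        assert w.beta == pytest.approx(0.4)

    def test_bimodal_simple_mode_tracks_majority(self):
        rng = np.random.default_rng(4)
        bx = np.full(10, 0.2)
        ratios = np.concatenate([rng.normal(0, 0.01, 7), rng.normal(1, 0.01, 3)])
        H = from_arrays(bx, np.full(10, 0.01), ratios * bx, np.full(10, 0.02))
        s, _ = mode_estimators(H, n_boot=50, seed=2)
        assert abs(s.beta) < 0.2

    def test_weighted_mode_tracks_heavy_cluster(self):
        rng = np.random.default_rng(5)
        bx = np.full(10, 0.2)
        ratios = np.concatenate([rng.normal(0, 0.01, 7), rng.normal(1, 0.01, 3)])
        sy = np.concatenate([np.full(7, 0.2), np.full(3, 0.005)])  # weight on ~1
        H = from_arrays(bx, np.full(10, 0.01), ratios * bx, sy)
        _, w = mode_estimators(H, n_boot=50, seed=3)
        assert abs(w.beta - 1) < 0.2


# ---------- invariance properties ----------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.1, 10.0))
def test_scale_equivariance(seed, c):
    """Scaling the outcome side by c scales every estimate and SE by c."""
    H, _ = simulate_harmonized(SimulationConfig(seed=seed, n_snp_instrument=8,
                                                theta=0.3))
    Hc = from_arrays(H.beta_x, H.se_x, c * H.beta_y, c * H.se_y)
    for fn in (lambda h: ivw_mre(h),
               lambda h: mr_egger(h)[0],
               lambda h: weighted_median(h, n_boot=60, seed=seed + 1)):
        e1, e2 = fn(H), fn(Hc)
        assert e2.beta == pytest.approx(c * e1.beta, rel=1e-6)
        assert e2.se == pytest.approx(c * e1.se, rel=0.3 if e1.method ==
                                      "weighted_median" else 1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_instrument_orientation_invariance(seed):
    """Jointly flipping (beta_x, beta_y) for a subset changes no estimate."""
    H, _ = simulate_harmonized(SimulationConfig(seed=seed, n_snp_instrument=9,
                                                theta=0.3))
    rng = np.random.default_rng(seed + 1)
    flip = rng.random(9) < 0.5
    sign = np.where(flip, -1.0, 1.0)
    Hf = from_arrays(sign * H.beta_x, H.se_x, sign * H.beta_y, H.se_y)
    assert ivw_mre(Hf).beta == pytest.approx(ivw_mre(H).beta, rel=1e-10)
    s1, s2 = mr_egger(H)[0], mr_egger(Hf)[0]
    assert s2.beta == pytest.approx(s1.beta, rel=1e-10)
    wm1 = weighted_median(H, n_boot=60, seed=3)
    wm2 = weighted_median(Hf, n_boot=60, seed=3)
    assert wm2.beta == pytest.approx(wm1.beta, rel=1e-10)
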