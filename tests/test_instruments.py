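import numpy as np
import pandas as pd
import pytest

from mrscreen.errors import MrScreenError
from mrscreen.instruments import (
    ClumpConfig,
    InsufficientInstruments,
    LDTable,
    clump,
    exclude_outcome_associated,
    filter_by_pvalue,
    per_snp_strength,
    select_instruments,
)

from conftest import make_dataset


def _ld(pairs):
    return LDTable(pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"]))


class TestPvalueFilter:
    def test_keeps_only_below_threshold(self):
        ds = make_dataset([{"snp": "a", "pval": 5e-6}, {"snp": "b", "pval": 2e-5}])
        kept = filter_by_pvalue(ds, 1e-5)
        assert list(kept.table["snp"]) == ["a"]

    def test_empty_dataset_gives_empty_subset(self):
        ds = make_dataset([])
        assert len(filter_by_pvalue(ds, 1e-5)) == 0

    def test_matches_exhaustive_scan_on_uniform_pvalues(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 1000)
        ds = make_dataset([{"snp": f"rs{i}", "pval": p[i]} for i in range(1000)])
        kept = filter_by_pvalue(ds, 0.05)
        assert len(kept) == int(np.sum(p < 0.05))

    def test_input_unchanged(self):
        ds = make_dataset([{"snp": "a", "pval": 0.5}])
        filter_by_pvalue(ds, 1e-5)
        assert len(ds) == 1


class TestClump:
    def test_single_snp_retained(self):
        ds = make_dataset([{"snp": "a", "pos": 100}])
        assert len(clump(ds, ClumpConfig())) == 1

    def test_correlated_cluster_keeps_best_pvalue(self):
        # three SNPs within 100 kb, pairwise r2 = 0.5: greedy keeps p = 1e-8
        ds = make_dataset([
            {"snp": "a", "pos": 1_000_000, "pval": 1e-8},
            {"snp": "b", "pos": 1_050_000, "pval": 1e-7},
            {"snp": "c", "pos": 1_100_000, "pval": 1e-6},
        ])
        ld = _ld([("a", "b", 0.5), ("a", "c", 0.5), ("b", "c", 0.5)])
        kept = clump(ds, ClumpConfig(ld_source=ld))
        assert list(kept.table["snp"]) == ["a"]

    def test_distance_window_bounds_ld_pruning(self):
        # 600 kb apart: outside the 500 kb window, both retained despite r2=0.9
        ds = make_dataset([
            {"snp": "a", "pos": 1_000_000, "pval": 1e-8},
            {"snp": "b", "pos": 1_600_000, "pval": 1e-7},
        ])
        kept = clump(ds, ClumpConfig(ld_source=_ld([("a", "b", 0.9)])))
        assert sorted(kept.table["snp"]) == ["a", "b"]

    def test_low_ld_neighbours_both_kept(self):
        ds = make_dataset([
            {"snp": "a", "pos": 1_000_000, "pval": 1e-8},
            {"snp": "b", "pos": 1_100_000, "pval": 1e-7},
        ])
        kept = clump(ds, ClumpConfig(ld_source=_ld([("a", "b", 0.005)])))
        assert sorted(kept.table["snp"]) == ["a", "b"]

    def test_distance_only_mode_is_conservative(self):
        ds = make_dataset([
            {"snp": "a", "pos": 1_000_000, "pval": 1e-8},
            {"snp": "b", "pos": 1_100_000, "pval": 1e-7},
        ])
        kept = clump(ds, ClumpConfig())  # no LD source
        assert list(kept.table["snp"]) == ["a"]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        ds = make_dataset([
            {"snp": f"rs{i}", "chrom": str(1 + i % 3),
             "pos": int(rng.integers(1, 5_000_000)), "pval": float(rng.uniform())}
            for i in range(40)
        ])
        once = clump(ds, ClumpConfig())
        twice = clump(once, ClumpConfig())
        assert list(once.table["snp"]) == list(twice.table["snp"])

    def test_retained_pairs_satisfy_window_or_ld_bound(self):
        rng = np.random.default_rng(6)
        snps = [f"rs{i}" for i in range(30)]
        pos = rng.integers(1, 3_000_000, 30)
        pairs = [(snps[i], snps[j], float(rng.uniform()))
                 for i in range(30) for j in range(i + 1, 30)]
        ld = _ld(pairs)
        ds = make_dataset([
            {"snp": snps[i], "pos": int(pos[i]), "pval": float(rng.uniform())}
            for i in range(30)
        ])
        cfg = ClumpConfig(ld_source=ld)
        kept = clump(ds, cfg).table
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                dist = abs(kept.iloc[i]["pos"] - kept.iloc[j]["pos"])
                r2 = ld.r2(kept.iloc[i]["snp"], kept.iloc[j]["snp"])
                assert dist >= cfg.window_bp or r2 < cfg.r2_max

    def test_missing_position_raises(self):
        ds = make_dataset([{"snp": "a", "pos": np.nan}])
        with pytest.raises(MrScreenError):
            clump(ds, ClumpConfig())


class TestStrength:
    def test_zero_beta_gives_zero(self):
        r2, f = per_snp_strength(0.0, 0.02, 1000)
        assert f == 0 and r2 == 0

    def test_closed_form(self):
        r2, f = per_snp_strength(0.1, 0.02, 7824)
        assert f == pytest.approx(25.0)
        assert r2 == pytest.approx(25.0 / (25.0 + 7822.0))

    def test_small_sample_rejected(self):
        with pytest.raises(MrScreenError):
            per_snp_strength(0.1, 0.02, 2)


class TestOutcomeExclusion:
    def test_outcome_associated_removed(self):
        ivs = make_dataset([{"snp": "a"}, {"snp": "b"}]).table
        outcome = make_dataset([{"snp": "a", "pval": 1e-7}, {"snp": "b", "pval": 0.3}])
        kept, excl = exclude_outcome_associated(ivs, outcome, 1e-5)
        assert list(kept["snp"]) == ["b"]
        assert excl["a"] == "outcome_associated"

    def test_absent_from_outcome_flagged(self):
        ivs = make_dataset([{"snp": "a"}]).table
        outcome = make_dataset([{"snp": "z", "pval": 0.5}])
        kept, excl = exclude_outcome_associated(ivs, outcome, 1e-5)
        assert len(kept) == 0
        assert excl["a"] == "not_in_outcome"


class TestSelect:
    def _exposure(self, n, strong=True):
        return make_dataset([
            {"snp": f"rs{i}", "chrom": str(1 + i % 22),
             "pos": 1_000_000 + 2_000_000 * (i // 22),
             "beta": 0.15 if strong else 0.001, "se": 0.02, }
            for i in range(n)
        ], n_total=7824)

    def _outcome(self, exposure):
        return make_dataset(
            [{"snp": s, "beta": 0.0, "se": 0.03, "pval": 0.5}
             for s in exposure.table["snp"]],
            trait_type="binary", n_total=365_120, n_cases=7306)

    def test_insufficient_when_fewer_than_min(self):
        exp = self._exposure(3)
        res = select_instruments(exp, self._outcome(exp), min_ivs=4)
        assert isinstance(res, InsufficientInstruments)
        assert res.count == 3

    def test_independent_genomewide_snps_all_retained(self):
        exp = self._exposure(20)
        res = select_instruments(exp, self._outcome(exp))
        assert len(res) == 20
        assert (res.table["f_stat"] > 10).all()

    def test_empty_exposure_flagged_zero(self):
        exp = make_dataset([{"snp": "a", "pval": 0.9}])
        res = select_instruments(exp, self._outcome(exp), min_ivs=4)
        assert isinstance(res, InsufficientInstruments) and res.count == 0

    def test_weak_instruments_filtered_by_f(self):
        # p just under threshold but F <= 10 must not survive
        exp = make_dataset([
            {"snp": f"rs{i}", "chrom": str(i + 1), "pos": 1_000_000,
             "beta": 0.09, "se": 0.02, "pval": 9e-6, "n": 12.0}
            for i in range(6)
        ])
        out = self._outcome(exp)
        res = select_instruments(exp, out, min_ivs=1)
        # F = (0.09/0.02)^2 = 20.25 > 10 with honest pval; force weak via n
        assert not isinstance(res, InsufficientInstruments)
        exp2 = make_dataset([
            {"snp": f"rs{i}", "chrom": str(i + 1), "pos": 1_000_000,
             "beta": 0.06, "se": 0.02, "pval": 9e-6}
            for i in range(6)
        ])
        res2 = select_instruments(exp2, self._outcome(exp2), min_ivs=1)
        assert isinstance(res2, InsufficientInstruments)  # F = 9 <= 10

    def test_row_order_invariance(self):
        exp = self._exposure(15)
        out = self._outcome(exp)
        shuffled = make_dataset([], n_total=7824)
        shuffled.table = exp.table.sample(frac=1, random_state=3).reset_index(drop=True)
        shuffled.meta = exp.meta
        a = select_instruments(exp, out)
        b = select_instruments(shuffled, out)
        assert list(a.table["snp"]) == list(b.table["snp"])

    def test_lower_threshold_never_increases_count(self):
        rng = np.random.default_rng(9)
        exp = make_dataset([
            {"snp": f"rs{i}", "chrom": str(1 + i % 22),
             "pos": 1_000_000 + 2_000_000 * (i // 22),
             "beta": float(rng.normal(0, 0.08)), "se": 0.02}
            for i in range(60)
        ], n_total=7824)
        out = self._outcome(exp)
        counts = []
        for thr in (1e-3, 1e-5, 1e-7):
            res = select_instruments(
                exp, out, ClumpConfig(p_threshold=thr), min_ivs=1)
            counts.append(0 if isinstance(res, InsufficientInstruments) else len(res))
        assert counts == sorted(counts, reverse=True)
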