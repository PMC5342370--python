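"""RPM, low-expression filtering, rank-sum DE, BH and stage patterns."""
import numpy as np
import pandas as pd
import pytest

from pirliver.expression import (
    bh_adjust,
    exact_rank_p,
    filter_low_expression,
    flag_high_expression,
    normalize_rpm,
    rank_sum_test,
    stage_patterns,
    wilcoxon_de,
)
from pirliver.simulate import simulate_counts

from conftest import small_sim_config


def _meta(groups):
    rows = []
    for stage, samples in groups.items():
        for i, s in enumerate(samples):
            rows.append({"sample": s, "patient": f"{stage}{i}", "stage": stage})
    return pd.DataFrame(rows)


class TestNormalizeRpm:
    def test_definitional_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
        rpm = normalize_rpm(counts, pd.Series({"s1": 100_000}))
        assert rpm.loc["a", "s1"] == 100.0
        assert rpm.loc["b", "s1"] == 0.0

    def test_column_sums_reach_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (30, 4)), columns=list("abcd"))
        rpm = normalize_rpm(counts, counts.sum(axis=0))
        assert np.allclose(rpm.sum(axis=0), 1e6)

    def test_zero_library_names_sample(self):
        counts = pd.DataFrame({"s1": [1], "bad": [0]})
        with pytest.raises(ValueError, match="bad"):
            normalize_rpm(counts, pd.Series({"s1": 10, "bad": 0}))


class TestLowExpressionFilter:
    meta = _meta({"CN": ["c1", "c2"], "pHCC": ["t1", "t2"]})

    def test_below_threshold_everywhere_removed(self):
        mat = pd.DataFrame({"c1": [0.4], "c2": [0.4], "t1": [0.7], "t2": [0.7]},
                           index=["f"])
        kept, report = filter_low_expression(mat, self.meta, 1.0)
        assert kept == [] and "f" in report.index

    def test_one_passing_group_retains(self):
        mat = pd.DataFrame({"c1": [0.4], "c2": [0.4], "t1": [2.0], "t2": [2.0]},
                           index=["f"])
        kept, _ = filter_low_expression(mat, self.meta, 1.0)
        assert kept == ["f"]

    def test_synthetic_planted_tail_recovered(self):
        cfg = small_sim_config(
            frac_low_expression=0.7, frac_differential=0.0,
            n_samples_per_stage={"CN": 5, "pHCC": 5},
        )
        ids = [f"f{i:03d}" for i in range(100)]
        counts, meta, truth = simulate_counts(cfg, ids)
        rpm = normalize_rpm(counts, counts.sum(axis=0))
        # toy library depth ~1.5k reads: one read is ~700 RPM, an expressed
        # feature ~3e4 RPM, so a 1000-RPM cut separates the planted tail
        kept, _ = filter_low_expression(rpm, meta, 1000.0)
        assert set(kept) == set(ids) - truth.low_expressed


class TestRankSumTest:
    def test_identical_multisets_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [3, 1, 2]) == 1.0

    def test_printed_example(self):
        assert exact_rank_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=7)
            p1 = rank_sum_test(x, y)
            p2 = rank_sum_test(np.exp(x), np.exp(y))
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5), rng.normal(size=6)
        assert rank_sum_test(x, y) == pytest.approx(rank_sum_test(y, x), abs=1e-12)

    def test_exact_close_to_asymptotic_at_eight(self):
        rng = np.random.default_rng(3)
        from scipy.stats import mannwhitneyu

        for _ in range(50):
            x, y = rng.normal(size=8), rng.normal(size=8)
            pe = exact_rank_p(x, y)
            pa = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert abs(pe - pa) <= 0.02

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestBhAdjust:
    def test_stepup_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_adjust([0.2]), [0.2])
        assert np.allclose(bh_adjust([0.05, 0.05]), [0.05, 0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_stepup_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            adj = bh_adjust(p)
            order = np.argsort(p, kind="stable")
            expected = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                running = min(running, p[order[rank]] * m / (rank + 1))
                expected[order[rank]] = running
            assert np.allclose(adj, expected, atol=1e-12)
            assert np.all(adj >= p - 1e-15)


class TestWilcoxonDe:
    meta = _meta({"CN": ["c1", "c2", "c3"], "pHCC": ["t1", "t2", "t3"]})

    def test_identical_groups_not_in_signature(self):
        mat = pd.DataFrame([[5, 6, 7, 7, 5, 6]], index=["f"],
                           columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        res = wilcoxon_de(mat, self.meta)
        assert res.loc["f", "p"] == 1.0
        assert res.loc["f", "fc"] == 1.0
        assert not res.loc["f", "in_signature"]

    def test_separated_groups_exact_p(self):
        mat = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["f"],
                           columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        res = wilcoxon_de(mat, self.meta)
        assert res.loc["f", "p"] == pytest.approx(0.1, abs=1e-12)

    def test_median_ratio_and_direction(self):
        mat = pd.DataFrame([[10, 10, 10, 30, 30, 30]], index=["f"],
                           columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        res = wilcoxon_de(mat, self.meta)
        assert res.loc["f", "fc"] == 3.0
        assert res.loc["f", "direction"] == "up"

    def test_group_swap_inverts_fc(self):
        mat = pd.DataFrame([[10, 12, 14, 29, 30, 31]], index=["f"],
                           columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        fwd = wilcoxon_de(mat, self.meta, "CN", "pHCC")
        rev = wilcoxon_de(mat, self.meta, "pHCC", "CN")
        assert fwd.loc["f", "p"] == pytest.approx(rev.loc["f", "p"], abs=1e-12)
        assert fwd.loc["f", "fc"] == pytest.approx(1 / rev.loc["f", "fc"])

    def test_zero_median_pseudocount(self):
        mat = pd.DataFrame([[0, 0, 0, 9.5, 9.5, 9.5]], index=["f"],
                           columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        res = wilcoxon_de(mat, self.meta)
        assert res.loc["f", "fc"] == pytest.approx((9.5 + 0.5) / 0.5)

    def test_paired_mode_runs(self):
        meta = _meta({"CN": ["c1", "c2", "c3"], "pHCC": ["t1", "t2", "t3"]})
        meta["patient"] = ["P1", "P2", "P3", "P1", "P2", "P3"]
        mat = pd.DataFrame([[1, 2, 3, 11, 12, 13]], index=["f"], columns=meta["sample"])
        res = wilcoxon_de(mat, meta, paired=True)
        assert 0 < res.loc["f", "p"] <= 1

    def test_too_small_group_rejected(self):
        meta = _meta({"CN": ["c1"], "pHCC": ["t1", "t2"]})
        mat = pd.DataFrame([[1, 2, 3]], index=["f"], columns=["c1", "t1", "t2"])
        with pytest.raises(ValueError, match="CN"):
            wilcoxon_de(mat, meta)


class TestStagePatterns:
    stages = {"CN": 4, "LGDN": 4, "HGDN": 4, "eHCC": 4, "pHCC": 4}

    def _matrix(self, level_by_stage, seed=0):
        rng = np.random.default_rng(seed)
        cols, vals = [], []
        for stage, n in self.stages.items():
            for i in range(n):
                cols.append(f"{stage}{i}")
                vals.append(level_by_stage.get(stage, 10.0) * rng.uniform(0.9, 1.1))
        meta = _meta({s: [f"{s}{i}" for i in range(n)] for s, n in self.stages.items()})
        return pd.DataFrame([vals], index=["f"], columns=cols), meta

    def test_flat(self):
        mat, meta = self._matrix({})
        res = stage_patterns(mat, meta)
        assert res.loc["f", "pattern"] == "flat"

    def test_lgdn_restricted(self):
        mat, meta = self._matrix({"LGDN": 300.0})
        res = stage_patterns(mat, meta)
        assert res.loc["f", "LGDN_vs_CN"] == "up"
        assert res.loc["f", "LGDN_vs_pHCC"] == "up"
        assert res.loc["f", "pattern"] == "LGDN-restricted"

    def test_up_from_hgdn(self):
        mat, meta = self._matrix({"HGDN": 300.0, "eHCC": 300.0, "pHCC": 300.0})
        res = stage_patterns(mat, meta)
        assert res.loc["f", "HGDN_vs_CN"] == "up"
        assert res.loc["f", "eHCC_vs_CN"] == "up"
        assert res.loc["f", "pattern"] == "up-from-HGDN"

    def test_down_from_lgdn(self):
        mat, meta = self._matrix(
            {"LGDN": 1.0, "HGDN": 1.0, "eHCC": 1.0, "pHCC": 1.0, "CN": 300.0}
        )
        res = stage_patterns(mat, meta)
        assert res.loc["f", "pattern"] == "down-from-LGDN"

    def test_phcc_restricted(self):
        mat, meta = self._matrix({"pHCC": 300.0})
        res = stage_patterns(mat, meta)
        assert res.loc["f", "pattern"] == "pHCC-restricted"

    def test_missing_stage_raises(self):
        mat, meta = self._matrix({})
        meta = meta[meta.stage != "HGDN"]
        mat = mat[[c for c in mat.columns if not c.startswith("HGDN")]]
        with pytest.raises(ValueError, match="HGDN"):
            stage_patterns(mat, meta)


class TestFlagHighExpression:
    meta = _meta({"CN": ["c1", "c2"], "pHCC": ["t1", "t2"]})

    def test_one_group_suffices(self):
        mat = pd.DataFrame({"c1": [6000.0], "c2": [6000.0], "t1": [10.0], "t2": [10.0]},
                           index=["f"])
        flagged, share = flag_high_expression(mat, self.meta)
        assert flagged == ["f"] and share == 1.0

    def test_empty_when_all_below(self):
        mat = pd.DataFrame({"c1": [10.0], "c2": [10.0], "t1": [10.0], "t2": [10.0]},
                           index=["f"])
        flagged, share = flag_high_expression(mat, self.meta)
        assert flagged == [] and share == 0.0

    def test_share_matches_direct_recomputation(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.uniform(0, 10_000, (20, 4)),
                           columns=["c1", "c2", "t1", "t2"])
        flagged, share = flag_high_expression(mat, self.meta, rpm_cutoff=5000)
        means = pd.DataFrame({
            "CN": mat[["c1", "c2"]].mean(axis=1), "pHCC": mat[["t1", "t2"]].mean(axis=1)})
        expect = mat.index[(means >= 5000).any(axis=1)]
        assert list(flagged) == list(expect)
        assert share == pytest.approx(mat.loc[expect].to_numpy().sum() / mat.to_numpy().sum())
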