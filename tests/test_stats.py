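"""Statistical tests: worked examples, symmetry, and the five analyses
on synthetic tidy-results fixtures."""

import numpy as np
import pandas as pd
import pytest

from coldstart_al.stats import (
    TIDY_COLUMNS,
    ZeroVarianceError,
    class_balance_correlation,
    compare_backbones,
    compare_encoders,
    init_vs_subsequent_correlation,
    oneshot_vs_full,
    paired_t_test,
    pearson_test,
    results_frame,
)


class TestPairedT:
    def test_df2_worked_example(self):
        # differences (1, 2, 3): t = mean / (sd / sqrt(3)) = 2 sqrt(3)
        res = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], "greater")
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.p_value == pytest.approx(0.0371, abs=5e-4)
        assert res.n_pairs == 3

    def test_constant_shift_is_degenerate(self):
        a = np.array([0.1, 0.5, 0.9])
        with pytest.raises(ZeroVarianceError):
            paired_t_test(a + 0.2, a, "two_sided")

    def test_swapping_arms_flips_sign_and_one_sided_p(self, rng):
        a = rng.random(8)
        b = rng.random(8)
        fwd = paired_t_test(a, b, "greater")
        rev = paired_t_test(b, a, "greater")
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value + rev.p_value == pytest.approx(1.0)

    def test_agrees_with_one_sample_t_on_differences(self, rng):
        from scipy import stats as sps

        a, b = rng.random(12), rng.random(12)
        res = paired_t_test(a, b, "two_sided")
        one = sps.ttest_1samp(a - b, 0.0)
        assert res.statistic == pytest.approx(one.statistic)
        assert res.p_value == pytest.approx(one.pvalue)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            paired_t_test([1.0, 2.0], [0.0, 0.0])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        res = pearson_test(x, 2 * x + 1, "greater")
        assert res.statistic == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = pearson_test([1, 2, 3, 4], [1, 3, 2, 4], "two_sided")
        assert res.statistic == pytest.approx(0.8)

    def test_invariance_under_joint_permutation(self, rng):
        x, y = rng.random(10), rng.random(10)
        perm = rng.permutation(10)
        assert pearson_test(x, y).statistic == pytest.approx(
            pearson_test(x[perm], y[perm]).statistic
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _frame(rows):
    defaults = {
        "run_id": "r0", "dataset": "d", "encoder": "e", "strategy": "s",
        "backbone": "image", "stage": "initialization", "budget": 10, "rep": 0,
        "metric": "auroc", "value": 0.5, "sd": 0.01, "minority_prop": 0.2,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=TIDY_COLUMNS)


def _encoder_fixture(delta, seed=0, n_cells=12):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cells):
        base = 0.6 + 0.2 * rng.random()
        for metric in ("auroc", "auprc"):
            rows.append({"encoder": "foundation", "strategy": f"s{i}", "metric": metric,
                         "value": base + delta + 0.01 * rng.normal()})
            rows.append({"encoder": "counterpart", "strategy": f"s{i}", "metric": metric,
                         "value": base + 0.01 * rng.normal()})
    return _frame(rows)


class TestCompareEncoders:
    def test_uniform_advantage_is_significant(self):
        df = _encoder_fixture(delta=0.1)
        results = compare_encoders(df, [("foundation", "counterpart")])
        assert all(r.p_value < 0.05 for r in results)

    def test_reversed_arms_complement_one_sided_p(self):
        df = _encoder_fixture(delta=0.1)
        fwd = compare_encoders(df, [("foundation", "counterpart")])
        rev = compare_encoders(df, [("counterpart", "foundation")])
        for f, r in zip(fwd, rev):
            assert f.p_value + r.p_value == pytest.approx(1.0)

    def test_identical_arms_degenerate(self):
        df = _encoder_fixture(delta=0.1)
        df["value"] = 0.7
        with pytest.raises(ZeroVarianceError):
            compare_encoders(df, [("foundation", "counterpart")])

    def test_unmatched_cells_rejected(self):
        df = _encoder_fixture(delta=0.1)
        with pytest.raises(ValueError, match="no matched cells"):
            compare_encoders(df, [("foundation", "missing")])


class TestCompareBackbones:
    def _fixture(self, delta, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(10):
            base = 0.7 + 0.1 * rng.random()
            rows.append({"backbone": "embedding", "strategy": f"s{i}",
                         "value": base - delta + 0.01 * rng.normal()})
            rows.append({"backbone": "image", "strategy": f"s{i}",
                         "value": base + 0.01 * rng.normal()})
        return _frame(rows)

    def test_inferior_embedding_arm_detected(self):
        results = compare_backbones(self._fixture(delta=0.1), metrics=("auroc",))
        assert all(r.p_value < 0.05 for r in results)

    def test_equal_arms_give_moderate_p(self):
        # under the null the one-sided p should average near 1/2
        ps = [
            compare_backbones(self._fixture(delta=0.0, seed=s), metrics=("auroc",))[0].p_value
            for s in range(200)
        ]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)


class TestInitVsSubsequent:
    def _fixture(self, coupling, seed=0, n_runs=20):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_runs):
            init = 0.6 + 0.2 * rng.random()
            rows.append({"run_id": f"r{i}", "stage": "initialization", "budget": 10, "value": init})
            for budget in (20, 30):
                later = coupling * init + (1 - abs(coupling)) * rng.random() * 0.2 + 0.05
                rows.append({"run_id": f"r{i}", "stage": "subsequent", "budget": budget,
                             "value": later})
        return _frame(rows)

    def test_coupled_stages_are_significant(self):
        results = init_vs_subsequent_correlation(self._fixture(coupling=1.0), metrics=("auroc",))
        assert {r.grouping for r in results} == {"dataset=d|budget=20", "dataset=d|budget=30"}
        assert all(r.p_value < 1e-6 for r in results)

    def test_anticorrelated_stages_have_large_one_sided_p(self):
        results = init_vs_subsequent_correlation(self._fixture(coupling=-1.0), metrics=("auroc",))
        assert all(r.p_value > 0.5 for r in results)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            init_vs_subsequent_correlation(self._fixture(coupling=1.0, n_runs=2), metrics=("auroc",))


class TestOneshotVsFull:
    def _fixture(self, delta, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(8):
            base = 0.7 + 0.1 * rng.random()
            rows.append({"strategy": f"s{i}", "stage": "initialization", "budget": 20,
                         "value": base - delta + 0.01 * rng.normal()})
            rows.append({"strategy": f"s{i}", "stage": "subsequent", "budget": 20,
                         "value": base + 0.01 * rng.normal()})
        return _frame(rows)

    def test_inferior_oneshot_detected(self):
        results = oneshot_vs_full(self._fixture(delta=0.1), metrics=("auroc",))
        assert all(r.p_value < 0.05 for r in results)

    def test_equal_arms_give_moderate_p(self):
        ps = [
            oneshot_vs_full(self._fixture(delta=0.0, seed=s), metrics=("auroc",))[0].p_value
            for s in range(200)
        ]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)

    def test_identical_arms_degenerate(self):
        df = self._fixture(delta=0.0)
        df["value"] = 0.8
        with pytest.raises(ZeroVarianceError):
            oneshot_vs_full(df, metrics=("auroc",))


class TestClassBalance:
    def _fixture(self, coupled, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(15):
            prop = rng.random() * 0.5
            value = prop if coupled else rng.random()
            rows.append({"run_id": f"r{i}", "rep": i, "minority_prop": prop, "value": value})
        return _frame(rows)

    def test_performance_equal_to_proportion_is_significant(self):
        results = class_balance_correlation(self._fixture(coupled=True), metrics=("auroc",))
        assert all(r.p_value < 1e-6 for r in results)

    def test_all_equal_proportions_degenerate(self):
        df = self._fixture(coupled=True)
        df["minority_prop"] = 0.2
        with pytest.raises(ZeroVarianceError):
            class_balance_correlation(df, metrics=("auroc",))

    def test_output_ordered_by_budget(self):
        df = pd.concat(
            [self._fixture(coupled=True).assign(budget=b) for b in (30, 10, 20)],
            ignore_index=True,
        )
        results = class_balance_correlation(df, metrics=("auroc",))
        budgets = [int(r.grouping.rsplit("=", 1)[1]) for r in results]
        assert budgets == sorted(budgets)


def test_results_frame_flattens_records():
    df = _encoder_fixture(delta=0.1)
    table = results_frame(compare_encoders(df, [("foundation", "counterpart")]))
    assert set(table.columns) == {
        "grouping", "metric", "test", "alternative", "statistic", "p_value", "n_pairs"
    }
    assert len(table) == 2  # one row per metric
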