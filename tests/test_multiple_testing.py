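import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from blockrar import (
    SpendingPlan,
    alpha_spending_monitor,
    closed_test_max_bonferroni,
    closed_test_pooled_z,
    holm_rejections,
)
from blockrar.weighting import adjusted_statistic, naive_z_statistic


class TestMaxBonferroniClosure:
    def test_worked_example(self):
        out = closed_test_max_bonferroni([3.0, 0.0], alpha=0.05)
        assert out.subset_decisions[frozenset({1, 2})]  # 3.0 >= 1.96
        assert out.subset_decisions[frozenset({1})]  # 3.0 >= 1.645
        assert not out.subset_decisions[frozenset({2})]
        np.testing.assert_array_equal(out.rejected, [True, False])

    def test_nothing_rejected_below_bonferroni_threshold(self):
        zcrit = stats.norm.ppf(1 - 0.05 / 3)
        out = closed_test_max_bonferroni([zcrit - 0.01] * 3, alpha=0.05)
        assert not out.rejected.any()

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        st.lists(st.floats(-4, 6, allow_nan=False), min_size=1, max_size=5),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_explicit_closure_equals_holm_shortcut(self, T, alpha):
        T = np.asarray(T)
        explicit = closed_test_max_bonferroni(T, alpha, shortcut=False)
        shortcut = closed_test_max_bonferroni(T, alpha, shortcut=True)
        np.testing.assert_array_equal(explicit.rejected, shortcut.rejected)
        # independent oracle: statsmodels' Holm step-down on the p-values
        ref = multipletests(special.ndtr(-T), alpha=alpha, method="holm")[0]
        np.testing.assert_array_equal(explicit.rejected, ref)

    def test_closure_is_monotone(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            T = rng.normal(size=4) + 1
            out = closed_test_max_bonferroni(T, 0.05, shortcut=False)
            for subset, dec in out.subset_decisions.items():
                if any(out.rejected[k - 1] for k in subset):
                    assert dec  # every subset containing a rejected arm is rejected

    def test_batched_holm(self):
        T = np.array([[3.0, 0.0], [0.0, 3.0], [2.5, 2.0]])
        out = holm_rejections(T, 0.05)
        np.testing.assert_array_equal(
            out, [[True, False], [False, True], [True, True]]
        )

    def test_nonfinite_statistics_rejected(self):
        with pytest.raises(ValueError):
            closed_test_max_bonferroni([np.nan, 1.0], 0.05)


class TestPooledClosedZ:
    def test_single_arm_reduces_to_elementary_test(self, trivial_trial):
        trial, aux = trivial_trial
        out = closed_test_pooled_z(trial, aux, statistic="adjusted")
        elem = adjusted_statistic(trial, aux, arm=1)
        assert out.statistics[0] == pytest.approx(float(elem.T), abs=1e-12)

    def test_trivial_case_matches_standard_pooled_z(self, trivial_trial):
        # realized = auxiliary: the pooled pseudo-arm statistic is the
        # classical pooled two-sample z
        trial, aux = trivial_trial
        out = closed_test_pooled_z(trial, aux, statistic="adjusted")
        pooled = np.concatenate([trial.arm_responses(1), trial.arm_responses(2)])
        z = (pooled.mean() - trial.control_mean()) / np.sqrt(
            1 / pooled.size + 1 / trial.design.n_control
        )
        assert out.subset_decisions[frozenset({1, 2})] == (z >= stats.norm.ppf(0.95))
        naive = closed_test_pooled_z(trial, aux, statistic="naive")
        for k in (1, 2):
            zk, _ = naive_z_statistic(trial.arm_responses(k), trial.arm_responses(0))
            assert naive.statistics[k - 1] == pytest.approx(zk, abs=1e-12)
            # trivial case: adjusted and naive statistics coincide
            assert out.statistics[k - 1] == pytest.approx(zk, abs=1e-12)


class TestAlphaSpending:
    def test_plan_validation(self):
        with pytest.raises(ValueError):
            SpendingPlan(looks=(2, 1), levels=(0.01, 0.04))
        with pytest.raises(ValueError):
            SpendingPlan(looks=(1, 2), levels=(0.06, -0.01))
        plan = SpendingPlan(looks=(1, 3), levels=(0.01, 0.04))
        assert plan.alpha == pytest.approx(0.05)
        assert plan.level_at(3) == 0.04
        with pytest.raises(ValueError, match="not a pre-specified look"):
            plan.level_at(2)

    def test_worked_example(self):
        plan = SpendingPlan(looks=(1, 2), levels=(0.01, 0.04))
        # T(1)=2.0 < 2.326 -> continue; T(2)=1.8 >= 1.751 -> reject
        res = alpha_spending_monitor(plan, {1: 2.0, 2: 1.8})
        assert res.decisions == (False, True)
        assert res.stopped_at == 2 and res.rejected

    def test_null_statistics_never_reject(self):
        plan = SpendingPlan(looks=(1, 2, 3), levels=(0.01, 0.02, 0.02))
        res = alpha_spending_monitor(plan, {1: 0.0, 2: 0.0, 3: 0.0})
        assert not res.rejected and res.decisions == (False, False, False)

    def test_unplanned_look_refused(self):
        plan = SpendingPlan(looks=(1, 3), levels=(0.025, 0.025))
        with pytest.raises(ValueError, match="unplanned"):
            alpha_spending_monitor(plan, {2: 5.0})

    def test_bonferroni_bound_under_null(self):
        # two looks on independent-increment-free statistics: total rejection
        # probability is bounded by the summed levels
        rng = np.random.default_rng(12)
        R = 40_000
        plan = SpendingPlan(looks=(1, 2), levels=(0.025, 0.025))
        T1 = rng.standard_normal(R)
        T2 = 0.7 * T1 + np.sqrt(1 - 0.49) * rng.standard_normal(R)
        z1, z2 = stats.norm.ppf(1 - 0.025), stats.norm.ppf(1 - 0.025)
        total = ((T1 >= z1) | (T2 >= z2)).mean()
        assert total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / R)
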