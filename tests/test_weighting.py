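import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from blockrar import (
    AuxiliaryDesign,
    adjusted_statistic,
    compute_weight_trace,
    naive_z_statistic,
    pooled_variance,
    VarianceEstimate,
)
from blockrar.design import tail_sums
from blockrar.weighting import adjusted_statistic_arrays, weight_trace_arrays

counts_pair = st.lists(
    st.tuples(st.integers(1, 60), st.integers(1, 60)), min_size=1, max_size=6
)


def oracle_weights(aux, realized, burn):
    """Per-block numeric root-finding of the variance-matching equation."""
    aux = np.asarray(aux, float)
    rea = np.asarray(realized, float)
    m = tail_sums(aux)
    B = aux.size
    w = [burn + m[0]]
    for j in range(1, B + 1):
        lhs = rea[j - 1] + (m[j] if j < B else 0.0)
        rhs = (aux[j - 1] + (m[j] if j < B else 0.0)) / w[-1] ** 2
        f = lambda x: lhs / x**2 - rhs
        w.append(optimize.brentq(f, 1e-9, 1e9, xtol=1e-12, rtol=1e-14))
    return np.array(w)


class TestWeightTrace:
    def test_worked_example(self):
        # n_k=10, burn-in 2, auxiliary blocks (4,4), realized (6,3)
        aux = AuxiliaryDesign(burn_in_counts=[2], alloc_counts=[[4], [4]])
        wt = compute_weight_trace(aux, [6, 3])
        np.testing.assert_allclose(
            wt.w, [10.0, 10 * np.sqrt(10 / 8), 10 * np.sqrt(10 / 8) * np.sqrt(3 / 4)]
        )
        np.testing.assert_allclose(wt.w, [10.0, 11.1803, 9.6825], atol=5e-5)
        np.testing.assert_allclose(wt.v, [0.2, 0.53666, 0.30984], atol=5e-6)

    def test_no_adaptation_collapses_to_totals(self):
        aux = AuxiliaryDesign(burn_in_counts=[5], alloc_counts=[[12], [9], [14]])
        wt = compute_weight_trace(aux, [12, 9, 14])
        np.testing.assert_allclose(wt.w, 40.0)
        np.testing.assert_allclose(wt.v_sum, 1.0, atol=1e-14)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(counts_pair, st.integers(1, 20))
    def test_matches_root_finder_oracle(self, pairs, burn):
        aux = [a for a, _ in pairs]
        rea = [r for _, r in pairs]
        wt = weight_trace_arrays(np.array(aux), np.array(rea), burn)
        np.testing.assert_allclose(wt.w, oracle_weights(aux, rea, burn), rtol=1e-10)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(counts_pair, st.integers(1, 20))
    def test_positivity_and_telescoping(self, pairs, burn):
        aux = np.array([a for a, _ in pairs], float)
        rea = np.array([r for _, r in pairs], float)
        wt = weight_trace_arrays(aux, rea, burn)
        assert (wt.w > 0).all()
        # per-block conditional variance identity:
        # realized_j/w_j^2 + m_{j+1}/w_j^2 = m_j/w_{j-1}^2
        m = np.r_[tail_sums(aux), 0.0]
        lhs = (rea + m[1:]) / wt.w[1:] ** 2
        rhs = m[:-1] / wt.w[:-1] ** 2
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)
        # hence the total conditional variance telescopes to 1/n_k
        total = burn / wt.w[0] ** 2 + (rea / wt.w[1:] ** 2).sum()
        np.testing.assert_allclose(total, 1.0 / wt.w[0], rtol=1e-10)

    def test_weight_ratio_tracks_over_allocation(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            B = rng.integers(1, 5)
            aux = rng.integers(1, 40, size=B)
            rea = rng.integers(1, 40, size=B)
            wt = weight_trace_arrays(aux, rea, 5)
            ratios = wt.w[1:] / wt.w[:-1]
            # over-allocated blocks push the weight up, under-allocated down
            assert np.all((ratios > 1) == (rea > aux))

    def test_linear_update_breaks_variance_identity(self):
        aux, rea = np.array([10.0, 10.0]), np.array([16.0, 4.0])
        wt = weight_trace_arrays(aux, rea, 5, update="linear")
        total = 5 / wt.w[0] ** 2 + (rea / wt.w[1:] ** 2).sum()
        assert abs(total - 1.0 / wt.w[0]) > 1e-3

    def test_nonpositive_counts_reported(self):
        with pytest.raises(ValueError, match="block 2"):
            weight_trace_arrays(np.array([4, 0]), np.array([4, 4]), 5)
        with pytest.raises(ValueError, match="realized"):
            weight_trace_arrays(np.array([4, 4]), np.array([4, 0]), 5)


class TestAdjustedStatistic:
    def test_trivial_case_equals_standard_z(self, trivial_trial):
        trial, aux = trivial_trial
        n0 = trial.design.n_control
        for k in (1, 2):
            adj = adjusted_statistic(trial, aux, arm=k)
            x = trial.arm_responses(k)
            z = (x.mean() - trial.control_mean()) / np.sqrt(1 / x.size + 1 / n0)
            assert abs(float(adj.T) - z) < 1e-12
            assert abs(float(adj.weights.v_sum) - 1.0) < 1e-12

    def test_zero_responses_give_null_midpoint(self, trivial_trial):
        trial, aux = trivial_trial
        trial.response[:] = 0.0
        adj = adjusted_statistic(trial, aux, arm=1)
        assert float(adj.U_star) == 0.0
        assert float(adj.T) == 0.0 and float(adj.p) == 0.5

    def test_batch_shape_broadcasts(self):
        adj = adjusted_statistic_arrays(
            np.full((7, 3), 10.0),
            np.full((7, 3), 10.0),
            5,
            np.zeros(7),
            np.zeros((7, 3)),
            np.zeros(7),
            20,
        )
        assert adj.T.shape == (7,)
        np.testing.assert_allclose(adj.weights.v_sum, 1.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma2"):
            adjusted_statistic_arrays(
                np.array([4.0]), np.array([4.0]), 2, 0.0, np.array([0.0]), 0.0, 10,
                sigma2=-1.0,
            )

    def test_estimated_variance_rescales(self, trivial_trial):
        trial, aux = trivial_trial
        a1 = adjusted_statistic(trial, aux, arm=1, sigma2=1.0)
        a4 = adjusted_statistic(trial, aux, arm=1, sigma2=4.0)
        np.testing.assert_allclose(float(a4.T), float(a1.T) / 2.0)


class TestPooledVariance:
    def test_hand_example(self):
        est, df = pooled_variance([[0, 2], [1, 3], [-1, 1]])
        assert df == 3
        assert est == pytest.approx(2.0)

    def test_constant_groups_give_zero(self):
        est, _ = pooled_variance([[1.5, 1.5], [3, 3, 3], [0, 0]])
        assert est == 0.0

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError, match="df"):
            pooled_variance([[1.0], [2.0], [3.0]])

    def test_unbiased_under_normal_sampling(self):
        rng = np.random.default_rng(3)
        sigma2, reps = 2.25, 3000
        est = VarianceEstimate()
        for _ in range(reps):
            groups = [rng.normal(m, np.sqrt(sigma2), size=8) for m in (0.0, 1.0, -0.5)]
            est.add_block(groups)
        df = est.dfs[0]
        se = np.sqrt(2 * sigma2**2 / df / reps)
        assert abs(est.combined - sigma2) < 3 * se


class TestNaiveZ:
    def test_arithmetic(self):
        z, p = naive_z_statistic(np.full(50, 1.0), np.zeros(50))
        assert z == pytest.approx(5.0)
        assert p == pytest.approx(1 - stats.norm.cdf(5.0))

    def test_equal_constant_samples(self):
        z, p = naive_z_statistic([2.0, 2.0], [2.0, 2.0, 2.0])
        assert z == 0.0 and p == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            naive_z_statistic([], [1.0])
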