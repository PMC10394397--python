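import numpy as np
import pytest

from blockrar import (
    ArmSummary,
    BarConfig,
    InflatorConfig,
    Scenario,
    allocate_block_bar,
    allocate_block_error_inflator,
    allocate_block_fixed,
    bar_probabilities,
    simulate_trial,
    standard_design,
)


def summary(counts, means):
    return ArmSummary(counts=np.asarray(counts), means=np.asarray(means))


class TestBarProbabilities:
    def test_single_arm_gets_everything(self):
        pi = bar_probabilities(summary([10, 4], [0.0, 3.0]))
        np.testing.assert_allclose(pi, [1.0])

    def test_symmetry_between_identical_arms(self):
        pi = bar_probabilities(summary([10, 6, 6], [0.0, 0.7, 0.7]))
        np.testing.assert_allclose(pi, [0.5, 0.5])

    def test_gamma_zero_is_equal_randomization(self):
        cfg = BarConfig(gamma=0.0)
        pi = bar_probabilities(summary([10, 3, 9, 5], [0.0, 2.0, -1.0, 0.4]), cfg)
        np.testing.assert_allclose(pi, 1 / 3)

    def test_probabilities_form_a_distribution(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            K = rng.integers(1, 5)
            s = summary(rng.integers(1, 30, K + 1), rng.normal(size=K + 1))
            pi = bar_probabilities(s)
            assert pi.sum() == pytest.approx(1.0)
            assert (pi > 0).all() and (pi < 1).all() or K == 1

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            BarConfig(gamma=-0.5)


class TestAllocators:
    def test_degenerate_probabilities_still_cover_every_arm(self):
        labels = allocate_block_bar(40, [1.0, 0.0], np.random.default_rng(2))
        counts = np.bincount(labels, minlength=3)[1:]
        assert counts[1] == 1 and counts[0] == 39

    def test_conservation_and_coverage(self):
        rng = np.random.default_rng(3)
        for K in (2, 3, 4):
            p = rng.dirichlet(np.ones(K))
            labels = allocate_block_bar(40, p, rng)
            counts = np.bincount(labels, minlength=K + 1)[1:]
            assert counts.sum() == 40 and (counts >= 1).all()

    def test_uniform_allocation_mean(self):
        rng = np.random.default_rng(4)
        reps = 2000
        counts = np.array(
            [np.bincount(allocate_block_fixed(40, 2, rng), minlength=3)[1:]
             for _ in range(reps)]
        )
        se = np.sqrt(40 * 0.25 / reps)
        assert np.all(np.abs(counts.mean(axis=0) - 20) < 3 * se)

    def test_bar_with_flat_probabilities_matches_fixed(self):
        labels_bar = allocate_block_bar(40, [0.5, 0.5], np.random.default_rng(11))
        labels_fixed = allocate_block_fixed(40, 2, np.random.default_rng(11))
        np.testing.assert_array_equal(labels_bar, labels_fixed)

    def test_block_too_small_rejected(self):
        with pytest.raises(ValueError):
            allocate_block_fixed(2, 3, np.random.default_rng(0))


class TestErrorInflator:
    def test_pre_crossing_counts(self):
        labels = allocate_block_error_inflator(40, 2, False, np.random.default_rng(0))
        counts = np.bincount(labels, minlength=3)[1:]
        np.testing.assert_array_equal(counts, [39, 1])

    def test_post_crossing_counts(self):
        rng = np.random.default_rng(0)
        labels = allocate_block_error_inflator(40, 3, True, rng)
        counts = np.bincount(labels, minlength=4)[1:]
        assert counts[0] == 1
        assert counts[1:].sum() == 39 and (counts[1:] >= 1).all()

    def test_threshold_boundary_counts_as_crossed(self):
        cfg = InflatorConfig(threshold=0.5)
        assert cfg.is_crossed(0.5)
        assert not cfg.is_crossed(0.4999)

    def test_crossing_is_absorbing_in_simulated_trials(self):
        # once the favored arm drops to one patient per block it never recovers
        design = standard_design(2)
        saw_crossing = False
        for seed in range(40):
            scenario = Scenario(
                design=design, mus=(0.0, 0.3, 0.0), scheme="inflator", seed=seed
            )
            trial, _ = simulate_trial(scenario, seed)
            fav = trial.realized_counts[1:, 0]
            crossed = fav == 1
            saw_crossing |= crossed.any()
            if crossed.any():
                assert crossed[np.argmax(crossed):].all()
        assert saw_crossing

    def test_never_crossing_keeps_bulk_on_favored_arm(self):
        design = standard_design(2)
        scenario = Scenario(
            design=design, mus=(0.0, -50.0, 0.0), scheme="inflator", seed=1
        )
        trial, _ = simulate_trial(scenario, 1)
        np.testing.assert_array_equal(trial.realized_counts[1:, 0], [39, 39, 39])
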