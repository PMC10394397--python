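import numpy as np
import pytest

from blockrar import (
    AuxiliaryDesign,
    RealizedTrial,
    TrialDesign,
    generate_auxiliary_design,
    standard_design,
)


@pytest.fixture
def design2():
    return standard_design(2)


@pytest.fixture
def design3():
    return standard_design(3)


@pytest.fixture
def small_design():
    return TrialDesign(
        K=2,
        burn_in_per_arm=3,
        aux_block_totals=(8, 8),
        control_block_sizes=(4, 4),
        alpha=0.05,
    )


def build_trial_from_labels(
    design: TrialDesign,
    aux: AuxiliaryDesign,
    rng: np.random.Generator,
    mus: tuple[float, ...] | None = None,
) -> RealizedTrial:
    """A realized trial whose allocations follow the auxiliary list exactly."""
    mus = np.zeros(design.K + 1) if mus is None else np.asarray(mus, float)
    blocks, arms = [], []
    blocks.append(np.zeros(design.control_burn_in + design.K * design.burn_in_per_arm, int))
    arms.append(
        np.r_[np.zeros(design.control_burn_in, int),
              np.repeat(np.arange(1, design.K + 1), design.burn_in_per_arm)]
    )
    assert aux.block_labels is not None
    for j, labels in enumerate(aux.block_labels, start=1):
        lab = np.r_[labels, np.zeros(design.control_block_sizes[j - 1], int)]
        blocks.append(np.full(lab.size, j))
        arms.append(lab)
    block = np.concatenate(blocks)
    arm = np.concatenate(arms)
    response = rng.normal(mus[arm], np.sqrt(design.sigma2))
    return RealizedTrial(design=design, block=block, arm=arm, response=response)


@pytest.fixture
def trivial_trial(small_design):
    """(trial, aux) pair in which realized allocations equal the auxiliary design."""
    rng = np.random.default_rng(7)
    aux = generate_auxiliary_design(small_design, rng)
    trial = build_trial_from_labels(small_design, aux, rng, mus=(0.0, 0.3, 0.8))
    return trial, aux
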