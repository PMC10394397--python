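"""Response-adaptive allocation engines for block-randomized trials.

Three block allocators are provided, all updating only at block boundaries
and all guaranteeing at least one patient per experimental arm per block
(empty arms are repaired by reassigning the last drawn patients):

* :func:`allocate_block_bar` — Bayesian adaptive randomization: arm
  probabilities proportional to a tempered posterior probability of beating
  the control.
* :func:`allocate_block_error_inflator` — an adversarial rule that piles
  patients onto a favored arm while its running mean stays below a
  threshold, then abandons it; designed to inflate the naive z-test's
  type I error.
* :func:`allocate_block_fixed` — equal randomization, the non-adaptive
  reference.

The control allocation is never adapted; these engines allocate the
experimental patients of one block and return 1-based arm labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .design import enforce_min_one

__all__ = [
    "BarConfig",
    "InflatorConfig",
    "ArmSummary",
    "bar_probabilities",
    "allocate_block_bar",
    "allocate_block_error_inflator",
    "allocate_block_fixed",
]


@dataclass(frozen=True)
class BarConfig:
    """Bayesian adaptive randomization settings.

    ``gamma`` tempers the posterior probabilities: 0 gives equal
    randomization, 1 raw posterior probabilities; 0.5 is the usual
    compromise.  The posterior model is conjugate normal with known
    variance ``sigma2`` and flat priors on all arm means.
    """

    gamma: float = 0.5
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class InflatorConfig:
    """Error-inflator rule settings: favored arm and its mean threshold."""

    threshold: float = 0.5
    favored_arm: int = 1

    def __post_init__(self) -> None:
        if self.favored_arm < 1:
            raise ValueError("favored_arm must be an experimental arm label >= 1")

    def is_crossed(self, mean):
        """Threshold semantics: "remains below" fails at equality, so a
        running mean exactly at the threshold counts as crossed."""
        return mean >= self.threshold


@dataclass(frozen=True)
class ArmSummary:
    """Accumulated per-arm sample sizes and means, control at index 0."""

    counts: np.ndarray  # (K+1,)
    means: np.ndarray  # (K+1,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.float64))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=np.float64))
        if np.any(self.counts < 1):
            raise ValueError("every arm (incl. control) needs at least one observation")


def bar_probabilities(summary: ArmSummary, cfg: BarConfig | None = None) -> np.ndarray:
    """Tempered-posterior randomization probabilities ``(π_1..π_K)``.

    With flat priors and known variance, the posterior probability that arm
    ``k`` beats the control is ``Φ((x̄_k − x̄_0)/sqrt(σ²/ñ_k + σ²/n_0))`` on
    all data accumulated so far; the allocation probability is proportional
    to its ``gamma``-th power.
    """
    cfg = cfg or BarConfig()
    n0, m0 = summary.counts[0], summary.means[0]
    nk, mk = summary.counts[1:], summary.means[1:]
    z = (mk - m0) / np.sqrt(cfg.sigma2 / nk + cfg.sigma2 / n0)
    post = special.ndtr(z)
    if cfg.gamma == 0.0:
        return np.full(nk.size, 1.0 / nk.size)
    weights = post**cfg.gamma
    total = weights.sum()
    if total == 0.0:  # all posteriors underflowed; fall back to equal split
        return np.full(nk.size, 1.0 / nk.size)
    return weights / total


def _labels_from_probs(
    rng: np.random.Generator, block_size: int, probs: np.ndarray
) -> np.ndarray:
    K = probs.size
    if block_size < K:
        raise ValueError(f"block size {block_size} cannot cover {K} arms")
    labels = rng.choice(np.arange(1, K + 1), size=block_size, p=probs)
    return enforce_min_one(labels, K)


def allocate_block_bar(
    block_size: int,
    probs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one block of arm labels i.i.d. from ``probs`` with the >=1 guard."""
    probs = np.asarray(probs, dtype=np.float64)
    return _labels_from_probs(rng, block_size, probs)


def allocate_block_error_inflator(
    block_size: int,
    K: int,
    crossed: bool,
    rng: np.random.Generator,
    cfg: InflatorConfig | None = None,
) -> np.ndarray:
    """One block of the error-inflator rule.

    Before the favored arm's running mean crosses the threshold, it receives
    all but one patient per other arm; afterwards it receives exactly one
    patient and the remainder are equally randomized over the other arms.
    ``crossed`` is the absorbing state flag evaluated at the block boundary
    (mean >= threshold counts as crossed).
    """
    cfg = cfg or InflatorConfig()
    fav = cfg.favored_arm
    if not 1 <= fav <= K:
        raise ValueError(f"favored arm {fav} outside 1..{K}")
    if block_size < K:
        raise ValueError(f"block size {block_size} cannot cover {K} arms")
    others = [a for a in range(1, K + 1) if a != fav]
    if not crossed:
        labels = np.full(block_size, fav, dtype=np.int64)
        labels[block_size - len(others) :] = others
        return labels
    if K == 1:
        return np.full(block_size, fav, dtype=np.int64)
    labels = np.empty(block_size, dtype=np.int64)
    labels[0] = fav
    labels[1:] = rng.choice(others, size=block_size - 1)
    return enforce_min_one(labels, K)


def allocate_block_fixed(
    block_size: int, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Equal randomization: uniform i.i.d. labels with the >=1 guard."""
    return _labels_from_probs(rng, block_size, np.full(K, 1.0 / K))
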