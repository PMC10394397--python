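"""Closed testing over the elementary hypotheses and alpha-spending looks.

Each elementary hypothesis ``H_k: μ_k = μ_0`` is rejected iff every
intersection hypothesis containing it is rejected at level ``α`` (closed
test procedure).  Two intersection tests are provided:

* the *pooled closed z-test*: the arms of an intersection are pooled into a
  single pseudo-arm and the variance-matched adjusted statistic (or the
  naive z) is computed for it against the control, rejected at ``z_{1−α}``;
* the *max-statistic (Bonferroni–Holm) test*: the intersection is rejected
  when ``max_k T_k >= Φ⁻¹(1 − α/|𝒦|)``; its closure coincides with Holm's
  step-down procedure on the per-arm p-values.

Interim monitoring splits ``α`` over pre-specified looks; by Bonferroni the
overall one-sided level is bounded by the sum of the per-look levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .design import AuxiliaryDesign, RealizedTrial
from .weighting import adjusted_statistic, naive_z_statistic

__all__ = [
    "TestOutcome",
    "SpendingPlan",
    "MonitorResult",
    "closed_test_pooled_z",
    "closed_test_max_bonferroni",
    "holm_rejections",
    "alpha_spending_monitor",
    "all_subsets",
]


@dataclass(frozen=True)
class TestOutcome:
    """Per-arm statistics and closed-test decisions.

    ``subset_decisions`` maps each nonempty subset of ``{1..K}`` to its
    intersection-test decision; ``rejected[k-1]`` is True iff every subset
    containing ``k`` was rejected.
    """

    method: str
    alpha: float
    statistics: np.ndarray  # (K,)
    p_values: np.ndarray  # (K,)
    rejected: np.ndarray  # (K,) bool
    subset_decisions: dict[frozenset, bool] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def all_subsets(K: int) -> list[tuple[int, ...]]:
    """All nonempty subsets of arm labels ``{1..K}``."""
    arms = range(1, K + 1)
    return [s for r in range(1, K + 1) for s in combinations(arms, r)]


def _closure(subset_rejected: Mapping[frozenset, np.ndarray], K: int) -> np.ndarray:
    """Elementary decisions from intersection decisions (batch-capable).

    Returns an array of shape ``(..., K)``: arm ``k`` is rejected iff every
    subset containing it is rejected.
    """
    out = None
    for subset, dec in subset_rejected.items():
        dec = np.asarray(dec, dtype=bool)
        if out is None:
            out = np.ones(dec.shape + (K,), dtype=bool)
        for k in subset:
            out[..., k - 1] &= dec
    assert out is not None
    return out


def closed_test_pooled_z(
    trial: RealizedTrial,
    aux: AuxiliaryDesign,
    alpha: float | None = None,
    statistic: str = "adjusted",
) -> TestOutcome:
    """Closed test with pooled pseudo-arm intersection tests.

    For every nonempty subset of experimental arms, the subset's burn-in,
    auxiliary and realized counts are summed block by block and its
    responses pooled; the resulting single pseudo-arm is tested against the
    control at level ``alpha`` with the adjusted statistic
    (``statistic="adjusted"``) or the naive z on realized sample sizes
    (``statistic="naive"``).
    """
    d = trial.design
    alpha = d.alpha if alpha is None else alpha
    zcrit = stats.norm.ppf(1 - alpha)
    stats_k = np.empty(d.K)
    subset_dec: dict[frozenset, bool] = {}
    for subset in all_subsets(d.K):
        if statistic == "adjusted":
            T = float(adjusted_statistic(trial, aux, arm=subset).T)
        elif statistic == "naive":
            pooled = np.concatenate([trial.arm_responses(a) for a in subset])
            T, _ = naive_z_statistic(pooled, trial.arm_responses(0), d.sigma2)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        subset_dec[frozenset(subset)] = T >= zcrit
        if len(subset) == 1:
            stats_k[subset[0] - 1] = T
    rejected = _closure(subset_dec, d.K)
    return TestOutcome(
        method=f"closed-pooled-z ({statistic})",
        alpha=alpha,
        statistics=stats_k,
        p_values=special.ndtr(-stats_k),
        rejected=rejected,
        subset_decisions=subset_dec,
    )


def holm_rejections(statistics: np.ndarray, alpha: float) -> np.ndarray:
    """Holm's step-down procedure on one-sided z-statistics (batch-capable).

    ``statistics`` has arms on the last axis; returns a boolean array of the
    same shape.  Equivalent to the explicit closure of the max-statistic
    intersection tests.
    """
    T = np.asarray(statistics, dtype=np.float64)
    K = T.shape[-1]
    p = special.ndtr(-T)
    order = np.argsort(p, axis=-1)
    p_sorted = np.take_along_axis(p, order, axis=-1)
    steps = alpha / (K - np.arange(K))
    ok = p_sorted <= steps
    # step-down: reject the i-th smallest only if all smaller ones rejected
    passed = np.cumprod(ok, axis=-1).astype(bool)
    out = np.empty_like(passed)
    np.put_along_axis(out, order, passed, axis=-1)
    return out


def closed_test_max_bonferroni(
    statistics: Sequence[float] | np.ndarray,
    alpha: float,
    shortcut: bool | None = None,
) -> TestOutcome:
    """Closed test with max-statistic / Bonferroni intersection tests.

    The explicit closure over all ``2^K − 1`` subsets is used for ``K <= 10``
    (or when ``shortcut=False``); the Holm shortcut otherwise.  The two are
    equivalent and the test suite checks they never disagree.
    """
    T = np.asarray(statistics, dtype=np.float64)
    if not np.all(np.isfinite(T)):
        raise ValueError("statistics must be finite")
    K = T.size
    use_shortcut = (K > 10) if shortcut is None else shortcut
    subset_dec: dict[frozenset, bool] = {}
    if use_shortcut:
        rejected = holm_rejections(T, alpha)
    else:
        for subset in all_subsets(K):
            zcrit = stats.norm.ppf(1 - alpha / len(subset))
            subset_dec[frozenset(subset)] = max(T[k - 1] for k in subset) >= zcrit
        rejected = _closure(subset_dec, K)
    return TestOutcome(
        method="holm" if use_shortcut else "closed-max-bonferroni",
        alpha=alpha,
        statistics=T,
        p_values=special.ndtr(-T),
        rejected=rejected,
        subset_decisions=subset_dec,
    )


@dataclass(frozen=True)
class SpendingPlan:
    """Pre-specified interim looks and the alpha spent at each.

    ``looks`` are adaptive block indices, strictly increasing, the last one
    being the final block; ``levels`` are the one-sided levels spent at each
    look, summing to the overall ``alpha``.
    """

    looks: tuple[int, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "looks", tuple(int(s) for s in self.looks))
        object.__setattr__(self, "levels", tuple(float(a) for a in self.levels))
        if len(self.looks) != len(self.levels) or not self.looks:
            raise ValueError("looks and levels must be non-empty and aligned")
        if any(s2 <= s1 for s1, s2 in zip(self.looks, self.looks[1:])):
            raise ValueError("looks must be strictly increasing block indices")
        if self.looks[0] < 1:
            raise ValueError("looks must be >= 1")
        if any(a < 0 for a in self.levels):
            raise ValueError("spending levels must be non-negative")

    @property
    def alpha(self) -> float:
        return float(sum(self.levels))

    def level_at(self, S: int) -> float:
        try:
            return self.levels[self.looks.index(S)]
        except ValueError:
            raise ValueError(f"block {S} is not a pre-specified look of the plan") from None


@dataclass(frozen=True)
class MonitorResult:
    """Per-look decisions of an alpha-spending monitor."""

    plan: SpendingPlan
    decisions: tuple[bool, ...]  # aligned with plan.looks, up to the stop
    stopped_at: int | None  # block index of the first rejection, or None

    @property
    def rejected(self) -> bool:
        return self.stopped_at is not None


def alpha_spending_monitor(
    plan: SpendingPlan, interim_stats: Mapping[int, float]
) -> MonitorResult:
    """Apply the Bonferroni spending rule to interim statistics.

    ``interim_stats`` maps block index ``S`` to ``T̃(S)``, computed by
    :func:`blockrar.weighting.interim_statistic` at the plan's looks only;
    statistics at unplanned looks are refused.  The hypothesis is rejected
    at the first look with ``T̃(S) >= Φ⁻¹(1 − α_S)``; the overall one-sided
    error is bounded by ``Σ α_S``.
    """
    unplanned = set(interim_stats) - set(plan.looks)
    if unplanned:
        raise ValueError(
            f"statistics supplied at unplanned looks {sorted(unplanned)}; "
            "monitoring times must be pre-specified"
        )
    decisions: list[bool] = []
    for S, level in zip(plan.looks, plan.levels):
        if S not in interim_stats:
            break
        reject = interim_stats[S] >= stats.norm.ppf(1 - level)
        decisions.append(bool(reject))
        if reject:
            return MonitorResult(plan=plan, decisions=tuple(decisions), stopped_at=S)
    return MonitorResult(plan=plan, decisions=tuple(decisions), stopped_at=None)
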