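"""Variance-matched weighting of the z-statistic for block-RAR trials.

The adjusted test compares a realized response-adaptive allocation against a
pre-fixed *auxiliary* allocation.  Writing ``n_{j,k}`` for the auxiliary and
``ñ_{j,k}`` for the realized count of arm ``k`` in block ``j``, and
``m_{j,k} = n_{j,k} + ... + n_{B,k}`` for auxiliary tail sums, the per-arm
weight sequence is

    w_0 = n_k                                   (auxiliary total, burn-in incl.)
    w_j = w_{j-1} * sqrt((ñ_{j,k} + m_{j+1,k}) / (n_{j,k} + m_{j+1,k}))
    w_B = w_{B-1} * sqrt(ñ_{B,k} / n_{B,k})

Each ``w_j`` is the unique positive solution of the conditional
variance-matching equation

    (ñ_{j,k} + m_{j+1,k}) / w_j**2  =  m_{j,k} / w_{j-1}**2 ,

so the running statistic keeps, block by block, the conditional variance it
would have had under the auxiliary design.  Because the update is a ratio of
positive counts, the weights can never turn negative, whatever the adaptive
scheme does.  The adjusted statistic

    Ũ  = (n_{0,k}/n_k) X̄_k(burn-in) + Σ_j (ñ_{j,k}/w_j) X̄_k(block j)
    Ũ* = Ũ − (Σ_j v_j) X̄_0(n_0),        v_j = ñ_{j,k}/w_j
    T̃  = Ũ* / [σ sqrt(1/n_k + (Σ_j v_j)² / n_0)]

is exactly N(0, 1) under the null hypothesis μ_k = μ_0 when σ² is known,
regardless of how the realized counts were chosen from past data.

All core routines are array-native: count and mean inputs may carry leading
batch axes (e.g. Monte-Carlo replicates), with blocks on the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .design import AuxiliaryDesign, RealizedTrial, tail_sums

__all__ = [
    "WeightTrace",
    "AdjustedStatistic",
    "VarianceEstimate",
    "compute_weight_trace",
    "weight_trace_arrays",
    "adjusted_statistic",
    "adjusted_statistic_arrays",
    "interim_statistic",
    "pooled_variance",
    "naive_z_statistic",
]


@dataclass(frozen=True)
class WeightTrace:
    """Weights ``w_0..w_B`` and contribution coefficients ``v_0..v_B``.

    ``v_j = ñ_{j,k} / w_j`` with ``ñ_{0,k} = n_{0,k}``; when the realized
    counts equal the auxiliary ones, every ``w_j`` collapses to the arm
    total ``n_k`` and ``Σ v_j = 1``.
    """

    w: np.ndarray  # (..., B+1)
    v: np.ndarray  # (..., B+1)

    @property
    def v_sum(self) -> np.ndarray:
        return self.v.sum(axis=-1)


@dataclass(frozen=True)
class AdjustedStatistic:
    """The adjusted statistic and its building blocks (batch-shaped)."""

    U0: np.ndarray
    U_tilde_blocks: np.ndarray  # (..., B)
    U_tilde: np.ndarray
    U_star: np.ndarray
    sd_star: np.ndarray
    T: np.ndarray
    p: np.ndarray
    weights: WeightTrace


def weight_trace_arrays(
    aux_counts: np.ndarray,
    realized_counts: np.ndarray,
    burn_in_count: np.ndarray | int,
    update: str = "sqrt",
) -> WeightTrace:
    """Compute the weight trace from per-block counts.

    Parameters
    ----------
    aux_counts, realized_counts : array, shape (..., B)
        Auxiliary and realized counts of one arm in adaptive blocks 1..B.
    burn_in_count : array or int
        The (shared) block-0 count ``n_{0,k}``.
    update : {"sqrt", "linear"}
        The variance-matching update (default) or the plain count-ratio
        update ``w_j = w_{j-1} (ñ+m)/(n+m)``.  The linear form does *not*
        match conditional variances and is kept only so tests can
        demonstrate that it miscalibrates the statistic.
    """
    aux = np.asarray(aux_counts, dtype=np.float64)
    rea = np.asarray(realized_counts, dtype=np.float64)
    burn = np.asarray(burn_in_count, dtype=np.float64)
    if aux.shape != rea.shape:
        raise ValueError("auxiliary and realized count arrays must share a shape")
    B = aux.shape[-1]
    if B < 1:
        raise ValueError("need at least one adaptive block")
    for name, arr in (("auxiliary", aux), ("realized", rea)):
        if np.any(arr < 1):
            j = int(np.argwhere(arr.reshape(-1, B) < 1)[0, 1])
            raise ValueError(f"nonpositive {name} count in block {j + 1}")
    if np.any(burn < 1):
        raise ValueError("nonpositive burn-in count")
    if update not in ("sqrt", "linear"):
        raise ValueError(f"unknown update rule {update!r}")

    m = tail_sums(aux, axis=-1)  # m[..., j-1] = m_{j,k}
    n_total = burn + m[..., 0]

    batch = aux.shape[:-1]
    w = np.empty(batch + (B + 1,))
    w[..., 0] = n_total
    for j in range(1, B):
        m_next = m[..., j]  # m_{j+1,k}
        ratio = (rea[..., j - 1] + m_next) / (aux[..., j - 1] + m_next)
        w[..., j] = w[..., j - 1] * (np.sqrt(ratio) if update == "sqrt" else ratio)
    ratio_B = rea[..., B - 1] / aux[..., B - 1]
    w[..., B] = w[..., B - 1] * (np.sqrt(ratio_B) if update == "sqrt" else ratio_B)

    v = np.empty_like(w)
    v[..., 0] = burn / w[..., 0]
    v[..., 1:] = rea / w[..., 1:]
    return WeightTrace(w=w, v=v)


def compute_weight_trace(
    aux: AuxiliaryDesign,
    realized_counts: Sequence[int] | np.ndarray,
    arm: int = 1,
    update: str = "sqrt",
) -> WeightTrace:
    """Weight trace for one arm of an auxiliary design (1-based label)."""
    k = arm - 1
    return weight_trace_arrays(
        aux.alloc_counts[:, k],
        np.asarray(realized_counts),
        aux.burn_in_counts[k],
        update=update,
    )


def adjusted_statistic_arrays(
    aux_counts: np.ndarray,
    realized_counts: np.ndarray,
    burn_in_count: np.ndarray | int,
    burn_in_mean: np.ndarray,
    block_means: np.ndarray,
    control_mean: np.ndarray,
    n_control: np.ndarray | int,
    sigma2: float | np.ndarray = 1.0,
    update: str = "sqrt",
) -> AdjustedStatistic:
    """Adjusted statistic from per-block counts and means (batch-capable).

    ``block_means[..., j-1]`` is the realized mean response of the arm in
    adaptive block ``j``; ``control_mean`` is the overall control mean over
    all blocks entering the analysis and ``n_control`` its sample size.
    """
    if np.any(np.asarray(sigma2) <= 0):
        raise ValueError("sigma2 must be positive")
    wt = weight_trace_arrays(aux_counts, realized_counts, burn_in_count, update=update)
    rea = np.asarray(realized_counts, dtype=np.float64)
    burn = np.asarray(burn_in_count, dtype=np.float64)
    n_total = wt.w[..., 0]

    U0 = burn / n_total * np.asarray(burn_in_mean)
    U_blocks = rea / wt.w[..., 1:] * np.asarray(block_means)
    U_tilde = U0 + U_blocks.sum(axis=-1)
    v_sum = wt.v_sum
    U_star = U_tilde - v_sum * np.asarray(control_mean)
    sd_star = np.sqrt(np.asarray(sigma2) * (1.0 / n_total + v_sum**2 / np.asarray(n_control)))
    T = U_star / sd_star
    p = special.ndtr(-T)  # one-sided, upper tail
    return AdjustedStatistic(
        U0=U0,
        U_tilde_blocks=U_blocks,
        U_tilde=U_tilde,
        U_star=U_star,
        sd_star=sd_star,
        T=T,
        p=p,
        weights=wt,
    )


def _arm_block_stats(
    trial: RealizedTrial, arms: Sequence[int], through_block: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Realized counts (B,), block means (B,) and burn-in mean of a (pooled) arm."""
    B = trial.design.n_blocks if through_block is None else through_block
    idx = [a - 1 for a in arms]
    counts = trial.realized_counts[:, idx].sum(axis=1)
    sums, _ = trial.block_sums()
    sums = sums[:, idx].sum(axis=1)
    if np.any(counts[1 : B + 1] < 1):
        j = int(np.argwhere(counts[1 : B + 1] < 1)[0])
        raise ValueError(f"no data for arm(s) {list(arms)} in block {j + 1}")
    burn_mean = sums[0] / counts[0]
    return counts[1 : B + 1], sums[1 : B + 1] / counts[1 : B + 1], float(burn_mean)


def adjusted_statistic(
    trial: RealizedTrial,
    aux: AuxiliaryDesign,
    arm: int | Sequence[int] = 1,
    sigma2: float | None = None,
) -> AdjustedStatistic:
    """Adjusted statistic ``T̃`` for one experimental arm of a realized trial.

    ``arm`` may be a sequence of arm labels, in which case the arms are
    pooled into a single pseudo-arm (auxiliary, burn-in and realized counts
    summed block by block, responses pooled) before the weighting algorithm
    runs — the construction the pooled closed z-test is built on.

    When ``sigma2`` is None the design's known variance is used; pass a
    pooled estimate for the estimated-variance (asymptotic) mode.
    """
    arms = [arm] if np.isscalar(arm) else list(arm)
    counts, means, burn_mean = _arm_block_stats(trial, arms)
    idx = [a - 1 for a in arms]
    return adjusted_statistic_arrays(
        aux.alloc_counts[:, idx].sum(axis=1),
        counts,
        int(aux.burn_in_counts[idx].sum()),
        burn_mean,
        means,
        trial.control_mean(),
        trial.design.n_control,
        sigma2=trial.design.sigma2 if sigma2 is None else sigma2,
    )


def interim_statistic(
    trial: RealizedTrial,
    aux: AuxiliaryDesign,
    S: int,
    arm: int | Sequence[int] = 1,
    sigma2: float | None = None,
) -> AdjustedStatistic:
    """Interim adjusted statistic ``T̃(S)`` after adaptive block ``S < B``.

    Identical algorithm with the horizon truncated at ``S``: auxiliary tail
    sums are recomputed within blocks ``1..S``, block ``S`` is treated with
    the final-block rule, and the control mean runs over blocks ``0..S``
    (valid because the control allocation per block is fixed by design).
    ``S`` must be one of the pre-specified looks of a monitoring plan —
    choosing the analysis time from the observed statistics would invalidate
    the calibration.
    """
    B = trial.design.n_blocks
    if not 1 <= S < B:
        raise ValueError(f"interim block S must satisfy 1 <= S < B={B}, got {S}")
    arms = [arm] if np.isscalar(arm) else list(arm)
    counts, means, burn_mean = _arm_block_stats(trial, arms, through_block=S)
    idx = [a - 1 for a in arms]
    d = trial.design
    n_ctrl_S = d.control_burn_in + sum(d.control_block_sizes[:S])
    return adjusted_statistic_arrays(
        aux.alloc_counts[:S, idx].sum(axis=1),
        counts,
        int(aux.burn_in_counts[idx].sum()),
        burn_mean,
        means,
        trial.control_mean(through_block=S),
        n_ctrl_S,
        sigma2=trial.design.sigma2 if sigma2 is None else sigma2,
    )


def pooled_variance(block_responses: Sequence[np.ndarray]) -> tuple[float, int]:
    """Pooled variance estimate of one block's responses across all arms.

    ``block_responses`` lists the response vectors of arms ``0..K`` (control
    first) within a single block.  Returns ``(sigma2_hat, df)`` with
    ``df = Σ_k ñ_{j,k} − K − 1``.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in block_responses]
    n = sum(g.size for g in groups)
    df = n - len(groups)
    if df < 1:
        raise ValueError(f"not enough observations in block: df = {df}")
    ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups if g.size)
    return ss / df, df


class VarianceEstimate:
    """Running combination of per-block pooled variance estimates.

    Block estimates are stochastically independent of the running means in
    this normal model, so each is consistent; the combined estimate averages
    them with equal weights ``1/(j+1)`` after block ``j``.
    """

    def __init__(self) -> None:
        self.per_block: list[float] = []
        self.dfs: list[int] = []

    def add_block(self, block_responses: Sequence[np.ndarray]) -> float:
        est, df = pooled_variance(block_responses)
        self.per_block.append(est)
        self.dfs.append(df)
        return est

    @property
    def combined(self) -> float:
        if not self.per_block:
            raise ValueError("no blocks accumulated")
        return float(np.mean(self.per_block))


def naive_z_statistic(
    arm_data: np.ndarray, control_data: np.ndarray, sigma2: float = 1.0
) -> tuple[float, float]:
    """Standard two-sample z-statistic on realized sample sizes.

    Treats the adaptive sample sizes as if fixed in advance; under
    response-adaptive allocation its level is *not* guaranteed.  Returns
    ``(z, one-sided p)``.
    """
    x = np.asarray(arm_data, dtype=np.float64)
    c = np.asarray(control_data, dtype=np.float64)
    if x.size == 0 or c.size == 0:
        raise ValueError("both samples must be non-empty")
    z = (x.mean() - c.mean()) / np.sqrt(sigma2 / x.size + sigma2 / c.size)
    return float(z), float(special.ndtr(-z))
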