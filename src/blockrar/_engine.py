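"""Vectorized Monte-Carlo engine for whole-trial simulation.

Everything the test statistics need is a function of per-arm, per-block
response sums and counts, so replicated trials are simulated in count/sum
space with all replicates advanced together through the block structure:
given the counts, a block's response sum for an arm with mean ``μ`` is
exactly ``N(c μ, c σ²)``.  This is distribution-identical to per-patient
simulation for every statistic the package computes, and keeps a full
operating-characteristics run (1e5 replicates) to a few seconds.

The object-based single-trial path lives in :mod:`blockrar.simulation`;
this module is internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .design import TrialDesign, enforce_min_one
from .multiple_testing import _closure, all_subsets, holm_rejections
from .rar_schemes import BarConfig, InflatorConfig
from .weighting import adjusted_statistic_arrays


@dataclass
class BatchTrials:
    """Count/sum representation of simulated replicate trials."""

    design: TrialDesign
    mus: np.ndarray  # (K+1,), control first
    exp_counts: np.ndarray  # (R, B+1, K), row 0 = burn-in
    exp_sums: np.ndarray  # (R, B+1, K)
    ctrl_counts: np.ndarray  # (B+1,), fixed by design
    ctrl_sums: np.ndarray  # (R, B+1)
    aux_counts: np.ndarray  # (R, B, K)

    @property
    def n_reps(self) -> int:
        return self.exp_counts.shape[0]

    def control_mean(self) -> np.ndarray:
        return self.ctrl_sums.sum(axis=1) / self.ctrl_counts.sum()


def _draw_counts(
    rng: np.random.Generator, n_reps: int, block_size: int, probs: np.ndarray
) -> np.ndarray:
    """Per-replicate block counts from i.i.d. label draws with the >=1 guard.

    ``probs`` is ``(K,)`` (shared) or ``(n_reps, K)``.  The guard mirrors the
    allocators': the last drawn patients are reassigned to any empty arms.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    K = probs.shape[-1]
    if K == 1:
        return np.full((n_reps, 1), block_size, dtype=np.int64)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random((n_reps, block_size))
    labels = (u[:, :, None] > cum[:, None, :-1]).sum(axis=-1)  # 0-based
    offsets = np.arange(n_reps)[:, None] * K
    counts = np.bincount((labels + offsets).ravel(), minlength=n_reps * K)
    counts = counts.reshape(n_reps, K)
    bad = np.flatnonzero((counts == 0).any(axis=1))
    for r in bad:
        fixed = enforce_min_one(labels[r] + 1, K)
        counts[r] = np.bincount(fixed, minlength=K + 1)[1:]
    return counts.astype(np.int64)


def _bar_probs(
    cum_counts: np.ndarray,
    cum_sums: np.ndarray,
    ctrl_n: float,
    ctrl_sums: np.ndarray,
    cfg: BarConfig,
) -> np.ndarray:
    """Tempered posterior allocation probabilities, batched over replicates."""
    K = cum_counts.shape[-1]
    if cfg.gamma == 0.0:
        return np.full_like(cum_counts, 1.0 / K, dtype=np.float64)
    mk = cum_sums / cum_counts
    m0 = ctrl_sums / ctrl_n
    z = (mk - m0[:, None]) / np.sqrt(cfg.sigma2 / cum_counts + cfg.sigma2 / ctrl_n)
    w = special.ndtr(z) ** cfg.gamma
    total = w.sum(axis=1, keepdims=True)
    w = np.where(total > 0, w, 1.0)
    return w / w.sum(axis=1, keepdims=True)


def _inflator_counts(
    rng: np.random.Generator,
    n_reps: int,
    block_size: int,
    K: int,
    crossed: np.ndarray,
    cfg: InflatorConfig,
) -> np.ndarray:
    fav = cfg.favored_arm - 1
    others = [k for k in range(K) if k != fav]
    pre = np.ones((n_reps, K), dtype=np.int64)
    pre[:, fav] = block_size - (K - 1)
    if K == 1:
        return pre
    post = np.ones((n_reps, K), dtype=np.int64)
    if K == 2:
        post[:, others[0]] = block_size - 1
    else:
        split = _draw_counts(
            rng, n_reps, block_size - 1, np.full(len(others), 1.0 / len(others))
        )
        post[:, others] = split
    return np.where(crossed[:, None], post, pre)


def simulate_batch(
    design: TrialDesign,
    mus: np.ndarray,
    scheme: str,
    n_reps: int,
    rng: np.random.Generator,
    scheme_cfg: BarConfig | InflatorConfig | None = None,
) -> BatchTrials:
    """Simulate ``n_reps`` whole trials under one allocation scheme.

    ``mus`` lists ``(μ_0, μ_1, ..., μ_K)``, control first.  A fresh uniform
    auxiliary design is drawn per replicate.  Fully reproducible given the
    generator state.
    """
    mus = np.asarray(mus, dtype=np.float64)
    K, B = design.K, design.n_blocks
    if mus.size != K + 1:
        raise ValueError(f"need K+1={K + 1} means (control first), got {mus.size}")
    if scheme not in ("bar", "inflator", "fixed"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "bar":
        bar_cfg = scheme_cfg if isinstance(scheme_cfg, BarConfig) else BarConfig(sigma2=design.sigma2)
    if scheme == "inflator":
        inf_cfg = scheme_cfg if isinstance(scheme_cfg, InflatorConfig) else InflatorConfig()
    sigma = np.sqrt(design.sigma2)
    R = n_reps

    exp_counts = np.zeros((R, B + 1, K), dtype=np.int64)
    exp_sums = np.zeros((R, B + 1, K))
    ctrl_counts = np.asarray([design.control_burn_in, *design.control_block_sizes])
    ctrl_sums = np.empty((R, B + 1))
    aux_counts = np.empty((R, B, K), dtype=np.int64)

    uniform = np.full(K, 1.0 / K)
    for j, total in enumerate(design.aux_block_totals):
        aux_counts[:, j] = _draw_counts(rng, R, total, uniform)

    b = design.burn_in_per_arm
    exp_counts[:, 0] = b
    exp_sums[:, 0] = mus[1:] * b + sigma * np.sqrt(b) * rng.standard_normal((R, K))
    ctrl_sums[:, 0] = mus[0] * ctrl_counts[0] + sigma * np.sqrt(ctrl_counts[0]) * rng.standard_normal(R)

    if scheme == "inflator":
        crossed = np.zeros(R, dtype=bool)

    for j in range(1, B + 1):
        cum_counts = exp_counts[:, :j].sum(axis=1)
        cum_sums = exp_sums[:, :j].sum(axis=1)
        block_size = design.aux_block_totals[j - 1]
        if scheme == "fixed":
            counts = _draw_counts(rng, R, block_size, uniform)
        elif scheme == "bar":
            probs = _bar_probs(
                cum_counts,
                cum_sums,
                float(ctrl_counts[:j].sum()),
                ctrl_sums[:, :j].sum(axis=1),
                bar_cfg,
            )
            counts = _draw_counts(rng, R, block_size, probs)
        else:
            fav = inf_cfg.favored_arm - 1
            fav_mean = cum_sums[:, fav] / cum_counts[:, fav]
            crossed |= inf_cfg.is_crossed(fav_mean)  # absorbing
            counts = _inflator_counts(rng, R, block_size, K, crossed, inf_cfg)
        exp_counts[:, j] = counts
        exp_sums[:, j] = mus[1:] * counts + sigma * np.sqrt(counts) * rng.standard_normal((R, K))
        cj = ctrl_counts[j]
        ctrl_sums[:, j] = mus[0] * cj + sigma * np.sqrt(cj) * rng.standard_normal(R)

    return BatchTrials(
        design=design,
        mus=mus,
        exp_counts=exp_counts,
        exp_sums=exp_sums,
        ctrl_counts=ctrl_counts,
        ctrl_sums=ctrl_sums,
        aux_counts=aux_counts,
    )


def subset_statistics(batch: BatchTrials) -> tuple[dict[frozenset, np.ndarray], dict[frozenset, np.ndarray], float]:
    """Adjusted and naive statistics for every nonempty arm subset.

    Returns ``(adjusted, naive, min_weight)`` where each dict maps a subset
    of 1-based arm labels to a ``(R,)`` statistic array, and ``min_weight``
    is the smallest weight encountered across all arms, subsets, blocks and
    replicates.
    """
    d = batch.design
    n0 = int(batch.ctrl_counts.sum())
    ctrl_mean = batch.control_mean()
    adjusted: dict[frozenset, np.ndarray] = {}
    naive: dict[frozenset, np.ndarray] = {}
    min_weight = np.inf
    for subset in all_subsets(d.K):
        idx = [a - 1 for a in subset]
        burn = d.burn_in_per_arm * len(idx)
        aux_c = batch.aux_counts[:, :, idx].sum(axis=-1)
        rea_c = batch.exp_counts[:, 1:, idx].sum(axis=-1)
        rea_s = batch.exp_sums[:, 1:, idx].sum(axis=-1)
        burn_mean = batch.exp_sums[:, 0, idx].sum(axis=-1) / burn
        adj = adjusted_statistic_arrays(
            aux_c,
            rea_c,
            burn,
            burn_mean,
            rea_s / rea_c,
            ctrl_mean,
            n0,
            sigma2=d.sigma2,
        )
        adjusted[frozenset(subset)] = adj.T
        min_weight = min(min_weight, float(adj.weights.w.min()))
        tot_c = batch.exp_counts[:, :, idx].sum(axis=(1, 2))
        tot_s = batch.exp_sums[:, :, idx].sum(axis=(1, 2))
        naive[frozenset(subset)] = (tot_s / tot_c - ctrl_mean) / np.sqrt(
            d.sigma2 / tot_c + d.sigma2 / n0
        )
    return adjusted, naive, min_weight


METHODS = ("naive_closed_z", "naive_holm", "new_closed_z", "new_holm")


def analyze_batch(
    batch: BatchTrials, alpha: float | None = None
) -> dict[str, np.ndarray | float]:
    """Elementary rejection decisions of all four analysis methods.

    Returns a dict with per-method boolean arrays of shape ``(R, K)`` under
    the keys of :data:`METHODS`, the per-arm statistic arrays
    ``adjusted_T`` / ``naive_T`` of shape ``(R, K)``, and ``min_weight``.
    """
    d = batch.design
    alpha = d.alpha if alpha is None else alpha
    K = d.K
    adjusted, naive, min_weight = subset_statistics(batch)
    zcrit = stats.norm.ppf(1 - alpha)
    adj_T = np.column_stack([adjusted[frozenset((k,))] for k in range(1, K + 1)])
    nai_T = np.column_stack([naive[frozenset((k,))] for k in range(1, K + 1)])
    out: dict[str, np.ndarray | float] = {
        "adjusted_T": adj_T,
        "naive_T": nai_T,
        "min_weight": min_weight,
    }
    out["new_closed_z"] = _closure({s: t >= zcrit for s, t in adjusted.items()}, K)
    out["naive_closed_z"] = _closure({s: t >= zcrit for s, t in naive.items()}, K)
    out["new_holm"] = holm_rejections(adj_T, alpha)
    out["naive_holm"] = holm_rejections(nai_T, alpha)
    return out
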