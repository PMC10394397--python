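"""Trial designs, auxiliary designs and realized trials.

A block response-adaptive trial compares ``K`` experimental arms against a
common control whose allocation is fixed by design.  Patients enter in a
burn-in block (block 0, equal fixed allocation) followed by ``B`` adaptive
blocks in which only the experimental allocation is response-adaptive.

The *auxiliary design* is a hypothetical randomization list fixed before the
trial (here: uniform draws over the experimental arms).  Under it the
standard z-test is valid; the adjusted test statistic of
:mod:`blockrar.weighting` is calibrated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "TrialDesign",
    "AuxiliaryDesign",
    "RealizedTrial",
    "generate_auxiliary_design",
    "tail_sums",
    "load_config",
    "CONFIG_KEYS",
]


@dataclass(frozen=True)
class TrialDesign:
    """Static design constants of a block-RAR trial.

    Parameters
    ----------
    K : int
        Number of experimental arms (>= 1).  Arm ``0`` is the control.
    burn_in_per_arm : int
        Patients per *experimental* arm in the burn-in block (block 0).
    aux_block_totals : tuple of int
        Total experimental patients per adaptive block ``1..B``.
    control_block_sizes : tuple of int
        Control patients per adaptive block ``1..B`` (fixed, never adapted).
    alpha : float
        One-sided test level.
    sigma2 : float
        Known response variance (responses are normal with this variance).
    burn_in_control : int or None
        Control patients in block 0; defaults to ``burn_in_per_arm``.
    """

    K: int
    burn_in_per_arm: int
    aux_block_totals: tuple[int, ...]
    control_block_sizes: tuple[int, ...]
    alpha: float = 0.05
    sigma2: float = 1.0
    burn_in_control: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "aux_block_totals", tuple(int(x) for x in self.aux_block_totals))
        object.__setattr__(
            self, "control_block_sizes", tuple(int(x) for x in self.control_block_sizes)
        )
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.burn_in_per_arm < 1:
            raise ValueError("burn_in_per_arm must be a positive integer")
        if len(self.aux_block_totals) < 1:
            raise ValueError("need at least one adaptive block")
        if len(self.control_block_sizes) != len(self.aux_block_totals):
            raise ValueError("control_block_sizes must have one entry per adaptive block")
        if any(x < 1 for x in self.aux_block_totals):
            raise ValueError("aux_block_totals must be positive integers")
        if any(x < 1 for x in self.control_block_sizes):
            raise ValueError("control_block_sizes must be positive integers")
        if any(x < self.K for x in self.aux_block_totals):
            raise ValueError(
                "every adaptive block must hold at least one patient per experimental arm"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.burn_in_control is not None and self.burn_in_control < 1:
            raise ValueError("burn_in_control must be a positive integer")

    @property
    def n_blocks(self) -> int:
        """Number of adaptive blocks ``B`` (burn-in not counted)."""
        return len(self.aux_block_totals)

    @property
    def control_burn_in(self) -> int:
        return self.burn_in_control if self.burn_in_control is not None else self.burn_in_per_arm

    @property
    def n_control(self) -> int:
        """Total control observations n0 (fixed by design)."""
        return self.control_burn_in + sum(self.control_block_sizes)

    @property
    def n_experimental(self) -> int:
        """Total experimental patients across burn-in and all blocks."""
        return self.K * self.burn_in_per_arm + sum(self.aux_block_totals)


def tail_sums(counts: Sequence[int] | np.ndarray, axis: int = -1) -> np.ndarray:
    """Tail sums ``m_j = counts[j] + ... + counts[B]`` along ``axis``.

    The (implicit) entry past the end is zero, i.e. ``m_{B+1} = 0``.
    """
    arr = np.asarray(counts)
    if arr.shape[axis] == 0:
        raise ValueError("counts must be non-empty")
    rev = np.flip(arr, axis=axis)
    return np.flip(np.cumsum(rev, axis=axis), axis=axis)


@dataclass(frozen=True)
class AuxiliaryDesign:
    """A pre-fixed hypothetical allocation of the experimental patients.

    ``alloc_counts[j, k]`` is the number of patients the auxiliary list
    assigns to experimental arm ``k+1`` in adaptive block ``j+1``;
    ``burn_in_counts[k]`` is the block-0 allocation (shared with the realized
    trial).  ``block_labels``, when present, holds the per-patient arm labels
    (1-based) of each adaptive block in draw order.
    """

    burn_in_counts: np.ndarray  # (K,)
    alloc_counts: np.ndarray  # (B, K)
    block_labels: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        bc = np.asarray(self.burn_in_counts, dtype=np.int64)
        ac = np.atleast_2d(np.asarray(self.alloc_counts, dtype=np.int64))
        object.__setattr__(self, "burn_in_counts", bc)
        object.__setattr__(self, "alloc_counts", ac)
        if ac.ndim != 2 or bc.ndim != 1 or ac.shape[1] != bc.shape[0]:
            raise ValueError("alloc_counts must be (B, K) and burn_in_counts (K,)")
        if np.any(ac < 1):
            j, k = np.argwhere(ac < 1)[0]
            raise ValueError(
                f"auxiliary design allocates no patient to arm {k + 1} in block {j + 1}"
            )
        if np.any(bc < 1):
            raise ValueError("burn-in must allocate at least one patient per arm")

    @property
    def K(self) -> int:
        return self.alloc_counts.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.alloc_counts.shape[0]

    @property
    def tail_sums(self) -> np.ndarray:
        """``m[j, k] = n_{j+1,k} + ... + n_{B,k}`` for j = 0..B-1."""
        return tail_sums(self.alloc_counts, axis=0)

    @property
    def totals(self) -> np.ndarray:
        """Per-arm totals ``n_k`` including the burn-in (``m_{0,k}``)."""
        return self.burn_in_counts + self.alloc_counts.sum(axis=0)

    def pooled(self, arms: Sequence[int]) -> "AuxiliaryDesign":
        """Pool a subset of arms (1-based labels) into a single pseudo-arm."""
        idx = [a - 1 for a in arms]
        return AuxiliaryDesign(
            burn_in_counts=self.burn_in_counts[idx].sum(keepdims=True),
            alloc_counts=self.alloc_counts[:, idx].sum(axis=1, keepdims=True),
        )


def _guarded_uniform_labels(rng: np.random.Generator, size: int, K: int) -> np.ndarray:
    """Draw ``size`` arm labels uniformly from ``{1..K}``; if some arm ends up
    empty, the last drawn patients are reassigned so every arm gets >= 1."""
    labels = rng.integers(1, K + 1, size=size)
    return enforce_min_one(labels, K)


def enforce_min_one(labels: np.ndarray, K: int) -> np.ndarray:
    """Reassign the last drawn patients to any experimental arms left empty.

    Labels are 1-based.  Repeats from the end of the block until every arm in
    ``1..K`` is represented; requires ``len(labels) >= K``.
    """
    if len(labels) < K:
        raise ValueError("block must hold at least one patient per arm")
    labels = np.array(labels, copy=True)
    pos = len(labels)
    while True:
        counts = np.bincount(labels, minlength=K + 1)[1 : K + 1]
        empty = np.flatnonzero(counts == 0) + 1
        if empty.size == 0:
            return labels
        take = slice(pos - empty.size, pos)
        labels[take] = empty
        pos -= empty.size


def generate_auxiliary_design(
    design: TrialDesign, seed: int | np.random.Generator
) -> AuxiliaryDesign:
    """Draw the uniform auxiliary randomization list for a design.

    Each experimental patient of block ``j`` is assigned an arm uniformly at
    random from ``{1..K}``; blocks in which some arm would end up with zero
    patients are repaired by reassigning the last drawn patients (the same
    guard the adaptive allocators use), so that every weight denominator in
    the adjusted statistic is positive.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = design.K
    labels = []
    counts = np.empty((design.n_blocks, K), dtype=np.int64)
    for j, total in enumerate(design.aux_block_totals):
        lab = _guarded_uniform_labels(rng, total, K)
        labels.append(lab)
        counts[j] = np.bincount(lab, minlength=K + 1)[1 : K + 1]
    return AuxiliaryDesign(
        burn_in_counts=np.full(K, design.burn_in_per_arm, dtype=np.int64),
        alloc_counts=counts,
        block_labels=tuple(labels),
    )


@dataclass
class RealizedTrial:
    """Per-patient record of what the adaptive trial actually produced.

    Arrays are aligned: patient ``i`` sits in adaptive ``block[i]`` (0 =
    burn-in), on ``arm[i]`` (0 = control, 1..K experimental) and produced
    ``response[i]``.
    """

    design: TrialDesign
    block: np.ndarray
    arm: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=np.int64)
        self.arm = np.asarray(self.arm, dtype=np.int64)
        self.response = np.asarray(self.response, dtype=np.float64)
        if not (self.block.shape == self.arm.shape == self.response.shape):
            raise ValueError("block, arm and response must be aligned 1-d arrays")
        d = self.design
        B, K = d.n_blocks, d.K
        if self.block.min(initial=0) < 0 or self.block.max(initial=0) > B:
            raise ValueError("block indices must lie in 0..B")
        if self.arm.min(initial=0) < 0 or self.arm.max(initial=0) > K:
            raise ValueError("arm labels must lie in 0..K")
        counts = self.realized_counts
        if np.any(counts[1:] < 1):
            j, k = np.argwhere(counts[1:] < 1)[0]
            raise ValueError(f"no patient on arm {k + 1} in block {j + 1}")
        if np.any(counts[0] != d.burn_in_per_arm):
            raise ValueError("burn-in counts must equal the design's burn-in allocation")
        ctrl = np.bincount(self.block[self.arm == 0], minlength=B + 1)
        expect = np.r_[d.control_burn_in, d.control_block_sizes]
        if np.any(ctrl != expect):
            raise ValueError("control counts per block must equal the designed sizes")

    @property
    def realized_counts(self) -> np.ndarray:
        """``(B+1, K)`` experimental counts, row 0 = burn-in."""
        d = self.design
        out = np.zeros((d.n_blocks + 1, d.K), dtype=np.int64)
        mask = self.arm > 0
        np.add.at(out, (self.block[mask], self.arm[mask] - 1), 1)
        return out

    def block_sums(self) -> tuple[np.ndarray, np.ndarray]:
        """Experimental response sums ``(B+1, K)`` and control sums ``(B+1,)``."""
        d = self.design
        sums = np.zeros((d.n_blocks + 1, d.K))
        mask = self.arm > 0
        np.add.at(sums, (self.block[mask], self.arm[mask] - 1), self.response[mask])
        ctrl = np.zeros(d.n_blocks + 1)
        np.add.at(ctrl, self.block[~mask], self.response[~mask])
        return sums, ctrl

    def control_mean(self, through_block: int | None = None) -> float:
        """Mean control response over blocks ``0..through_block`` (default: all)."""
        mask = self.arm == 0
        if through_block is not None:
            mask &= self.block <= through_block
        return float(self.response[mask].mean())

    def arm_responses(self, k: int) -> np.ndarray:
        """All responses on arm ``k`` (0 = control)."""
        return self.response[self.arm == k]


CONFIG_KEYS = {
    "K": True,
    "burn_in_per_arm": True,
    "aux_block_totals": True,
    "control_block_sizes": True,
    "alpha": True,
    "sigma2": False,
    "burn_in_control": False,
    "scheme": False,
    "gamma": False,
    "threshold": False,
    "favored_arm": False,
    "seed": False,
}


def load_config(path: str) -> dict:
    """Read and validate a YAML design configuration.

    Required keys: ``K, burn_in_per_arm, aux_block_totals,
    control_block_sizes, alpha``.  Optional: ``sigma2, burn_in_control,
    scheme, gamma, threshold, favored_arm, seed``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path!r} must hold a key/value mapping")
    for key, required in CONFIG_KEYS.items():
        if required and key not in cfg:
            raise KeyError(f"missing required configuration key: {key!r}")
    unknown = set(cfg) - set(CONFIG_KEYS)
    if unknown:
        raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
    return cfg


def design_from_config(cfg: dict) -> TrialDesign:
    """Build a :class:`TrialDesign` from a validated configuration mapping."""
    return TrialDesign(
        K=int(cfg["K"]),
        burn_in_per_arm=int(cfg["burn_in_per_arm"]),
        aux_block_totals=tuple(cfg["aux_block_totals"]),
        control_block_sizes=tuple(cfg["control_block_sizes"]),
        alpha=float(cfg["alpha"]),
        sigma2=float(cfg.get("sigma2", 1.0)),
        burn_in_control=cfg.get("burn_in_control"),
    )
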