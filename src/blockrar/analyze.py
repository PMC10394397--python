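"""Re-analysis of a recorded block-RAR trial from a per-patient table.

The input is a delimited text table with header ``block,arm,response``:
``block`` 0 is the burn-in, ``arm`` 0 the control and ``1..K`` the
experimental arms.  The analysis recomputes, per experimental arm, the naive
z-statistic and the variance-matched adjusted statistic with its weight
trace, and runs both closed testing procedures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import AuxiliaryDesign, RealizedTrial, TrialDesign
from .multiple_testing import closed_test_max_bonferroni, closed_test_pooled_z
from .weighting import adjusted_statistic, naive_z_statistic

__all__ = ["read_trial_csv", "arm_table", "decision_table", "reanalyze"]

REQUIRED_COLUMNS = ("block", "arm", "response")


def read_trial_csv(path: str, design: TrialDesign) -> RealizedTrial:
    """Load per-patient records; validates counts against the design."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path!r} lacks required columns {missing}")
    return RealizedTrial(
        design=design,
        block=df["block"].to_numpy(),
        arm=df["arm"].to_numpy(),
        response=df["response"].to_numpy(),
    )


def arm_table(trial: RealizedTrial, aux: AuxiliaryDesign) -> pd.DataFrame:
    """Per-arm summary: naive z, adjusted T, p-values, weights and v_sum."""
    rows = {}
    for k in range(1, trial.design.K + 1):
        z, zp = naive_z_statistic(
            trial.arm_responses(k), trial.arm_responses(0), trial.design.sigma2
        )
        adj = adjusted_statistic(trial, aux, arm=k)
        row = {
            "n_realized": int(trial.realized_counts[:, k - 1].sum()),
            "n_auxiliary": int(aux.totals[k - 1]),
            "z_naive": z,
            "p_naive": zp,
            "T_adjusted": float(adj.T),
            "p_adjusted": float(adj.p),
            "v_sum": float(adj.weights.v_sum),
        }
        row.update({f"w{j}": float(w) for j, w in enumerate(adj.weights.w)})
        rows[k] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "arm"
    return out


def decision_table(
    trial: RealizedTrial, aux: AuxiliaryDesign, alpha: float | None = None
) -> pd.DataFrame:
    """Closed-test decisions per arm for all four analysis methods."""
    alpha = trial.design.alpha if alpha is None else alpha
    outcomes = {
        "new_closed_z": closed_test_pooled_z(trial, aux, alpha, statistic="adjusted"),
        "naive_closed_z": closed_test_pooled_z(trial, aux, alpha, statistic="naive"),
    }
    for label, key in (("new_holm", "new_closed_z"), ("naive_holm", "naive_closed_z")):
        outcomes[label] = closed_test_max_bonferroni(outcomes[key].statistics, alpha)
    rows = []
    for method, oc in outcomes.items():
        for k in range(1, trial.design.K + 1):
            rows.append(
                {
                    "method": method,
                    "arm": k,
                    "statistic": float(oc.statistics[k - 1]),
                    "p": float(oc.p_values[k - 1]),
                    "reject": bool(oc.rejected[k - 1]),
                }
            )
    return pd.DataFrame(rows)


def reanalyze(
    trial: RealizedTrial, aux: AuxiliaryDesign, alpha: float | None = None
) -> dict[str, pd.DataFrame]:
    """Full re-analysis: per-arm statistics and per-method decisions."""
    return {
        "arms": arm_table(trial, aux),
        "decisions": decision_table(trial, aux, alpha),
    }
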