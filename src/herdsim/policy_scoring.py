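"""Score candidate target-selection policies against observed orders.

Two scoring modes mirror the two-phase analysis of selection behaviour:

* *non-exclusive*: each policy is credited independently whenever its
  predicted order exactly matches the observed order (no partial credit);
* *exclusive*: policies are ranked by non-exclusive accuracy and each trial
  is assigned to the first (highest-ranked) policy that matches it, or to
  an ``other`` category, yielding proportions that partition the trials.

The observed order of a trial is operationalized as the order of first
herder-influence events, the only selection event a trajectory log
instruments.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .policies import IncompleteTrialError, PolicySpec, predict_order
from .simulator import TrajectoryLog

__all__ = [
    "observed_order",
    "score_non_exclusive",
    "classify_exclusive",
    "score_policies",
    "threshold_sweep",
]

OTHER = "other"


def observed_order(log: TrajectoryLog) -> list[int]:
    """Target ids ordered by the time of their first herder-influence event.

    Simultaneous first events (same sample) are broken by target id.
    """
    idx = log.first_influence_indices()
    missing = np.flatnonzero(idx < 0)
    if missing.size:
        raise IncompleteTrialError(
            f"targets {missing.tolist()} were never influenced; "
            "observed order undefined")
    return sorted(range(log.n_tas), key=lambda j: (idx[j], j))


def _matches(spec: PolicySpec, log: TrajectoryLog, obs: list[int]) -> bool:
    try:
        return predict_order(spec, log) == obs
    except IncompleteTrialError:
        return False


def score_non_exclusive(
    policies: Mapping[str, PolicySpec],
    trials: Sequence[TrajectoryLog],
) -> pd.DataFrame:
    """Independent exact-order match counts and proportions per policy."""
    if len(trials) == 0:
        raise ValueError("at least one trial is required")
    observed = [observed_order(log) for log in trials]
    rows = {}
    for name, spec in policies.items():
        n = sum(_matches(spec, log, obs) for log, obs in zip(trials, observed))
        rows[name] = {"nonexcl_N": n, "nonexcl_P": n / len(trials)}
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_exclusive(
    policies: Mapping[str, PolicySpec],
    trials: Sequence[TrajectoryLog],
    rank: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stepwise mutually exclusive assignment of trials to ranked policies.

    ``rank`` defaults to descending non-exclusive accuracy on these same
    trials, ties broken by the catalogue (mapping) order.  Unmatched trials
    fall into the ``other`` row; exclusive proportions sum to 1.
    """
    if rank is None:
        nonexcl = score_non_exclusive(policies, trials)
        pos = {name: k for k, name in enumerate(policies)}
        rank = sorted(policies, key=lambda n: (-nonexcl.loc[n, "nonexcl_N"], pos[n]))
    observed = [observed_order(log) for log in trials]
    counts = {name: 0 for name in policies}
    counts[OTHER] = 0
    for log, obs in zip(trials, observed):
        for name in rank:
            if _matches(policies[name], log, obs):
                counts[name] += 1
                break
        else:
            counts[OTHER] += 1
    total = len(trials)
    return pd.DataFrame(
        {"excl_N": pd.Series(counts),
         "excl_P": pd.Series({k: v / total for k, v in counts.items()})}
    )


def score_policies(
    policies: Mapping[str, PolicySpec],
    trials: Sequence[TrajectoryLog],
) -> pd.DataFrame:
    """Combined exclusive + non-exclusive score table (one row per policy)."""
    nonexcl = score_non_exclusive(policies, trials)
    excl = classify_exclusive(policies, trials)
    out = excl.join(nonexcl, how="left")
    out.loc[OTHER, ["nonexcl_N", "nonexcl_P"]] = [0, 0.0]
    out.index.name = "policy"
    return out


def threshold_sweep(
    trials: Sequence[TrajectoryLog],
    thresholds: Sequence[float],
    base: PolicySpec | None = None,
    participants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Non-exclusive SCA accuracy as a function of the collinear threshold.

    With ``participants`` given (one label per trial), a column per
    participant is returned alongside the pooled accuracy.
    """
    if len(thresholds) == 0:
        raise ValueError("at least one threshold is required")
    if len(trials) == 0:
        raise ValueError("at least one trial is required")
    from .policies import SCA

    base = base or SCA
    observed = [observed_order(log) for log in trials]
    rows = []
    for tau in thresholds:
        spec = base.with_threshold(tau)
        hit = np.array([_matches(spec, log, obs)
                        for log, obs in zip(trials, observed)])
        row = {"threshold_deg": tau, "accuracy": float(hit.mean())}
        if participants is not None:
            labels = np.asarray(participants)
            for p in dict.fromkeys(participants):
                row[str(p)] = float(hit[labels == p].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold_deg")
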