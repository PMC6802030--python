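"""Equilibrium summary statistics and fitness power from event logs.

Statistics are computed over a post-burn-in window of iterations.  State
(distance to optimum, fitness) is sampled once per iteration — at the end of
the iteration, after all of its proposal rounds — so regimes with different
round counts are sampled comparably.  Fixation statistics use each party's
own proposals within the window: the fixation fraction's denominator is that
party's window proposals, which stays comparable across mutational-input
multipliers.

Fitness power measures who is winning a two-party conflict:

    P_w1 = 1 - L1 / (L1 + L2)

where ``L_i`` is party i's mean lag load (1 - fitness) over the window.  It
ranges from 0 to 1; 0.5 means equal lag loads, values above 0.5 mean party 1
holds the joint phenotype closer to its own optimum.  Power is computed per
replicate from that replicate's mean lag loads, then averaged across
replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EquilibriumSummary",
    "PowerResult",
    "summarize_window",
    "fitness_power",
    "aggregate_replicates",
    "SUMMARY_FIELDS",
]

#: Per-replicate statistic columns aggregated across replicates.
SUMMARY_FIELDS = (
    "mean_distance",
    "mean_fitness",
    "fixation_fraction",
    "mean_fixation_size",
    "mean_lag_load",
    "power_party1",
)


@dataclass(frozen=True)
class EquilibriumSummary:
    """Equilibrium-window statistics for one party of one replicate.

    ``mean_fixation_size`` is NaN (missing, not zero) when the party fixed
    nothing in the window.  ``mean_lag_load`` equals ``1 - mean_fitness``
    exactly (same window, same samples).
    """

    party_index: int
    mean_distance: float
    mean_fitness: float
    fixation_fraction: float
    mean_fixation_size: float
    mean_lag_load: float
    n_proposals: int
    n_fixations: int


@dataclass(frozen=True)
class PowerResult:
    """Fitness power of party 1 and the mean lag loads behind it.

    ``power_party1`` is NaN when both parties sit at maximal fitness
    (L1 + L2 = 0), where power is undefined.
    """

    power_party1: float
    mean_L1: float
    mean_L2: float


def summarize_window(
    log: pd.DataFrame, burn_in: int, window: int
) -> dict[int, EquilibriumSummary]:
    """Summarize an event log over iterations ``[burn_in, burn_in + window)``.

    The log must have the event-log columns and a constant number of rows
    per iteration (as produced by the run functions).  Returns one
    :class:`EquilibriumSummary` per party present in the log, keyed by
    party index.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n_logged = int(log["iteration"].max()) + 1 if len(log) else 0
    if burn_in + window > n_logged:
        raise ValueError(
            f"window [{burn_in}, {burn_in + window}) exceeds log length {n_logged}"
        )
    sub = log[(log["iteration"] >= burn_in) & (log["iteration"] < burn_in + window)]
    rows_per_iter = len(sub) // window
    if rows_per_iter * window != len(sub):
        raise ValueError("event log must have a constant number of rows per iteration")
    end = sub.iloc[rows_per_iter - 1 :: rows_per_iter]
    z_end = end["z_after"].to_numpy()

    parties = [1]
    if (sub["party"] == 2).any() or not end["optimum2"].isna().all():
        parties.append(2)

    out: dict[int, EquilibriumSummary] = {}
    for p in parties:
        o_end = end[f"optimum{p}"].to_numpy()
        w_end = end[f"w{p}_after"].to_numpy()
        mean_fitness = float(np.mean(w_end))
        own = sub[sub["party"] == p]
        n_prop = int(len(own))
        fixed = own["fixed"].to_numpy()
        n_fix = int(fixed.sum())
        if n_fix > 0:
            mean_size = float(np.abs(own["effect"].to_numpy()[fixed]).mean())
        else:
            mean_size = math.nan
        out[p] = EquilibriumSummary(
            party_index=p,
            mean_distance=float(np.mean(np.abs(z_end - o_end))),
            mean_fitness=mean_fitness,
            fixation_fraction=(n_fix / n_prop) if n_prop else 0.0,
            mean_fixation_size=mean_size,
            mean_lag_load=1.0 - mean_fitness,
            n_proposals=n_prop,
            n_fixations=n_fix,
        )
    return out


def fitness_power(summaries: dict[int, EquilibriumSummary]) -> PowerResult:
    """Fitness power of party 1 from both parties' window summaries."""
    if set(summaries) != {1, 2}:
        raise ValueError("fitness power requires summaries for parties 1 and 2")
    L1 = summaries[1].mean_lag_load
    L2 = summaries[2].mean_lag_load
    total = L1 + L2
    power = math.nan if total == 0.0 else 1.0 - L1 / total
    return PowerResult(power_party1=power, mean_L1=L1, mean_L2=L2)


def _as_frame(per_replicate) -> pd.DataFrame:
    """Accept the per-replicate frame or lists of summary/power objects."""
    if isinstance(per_replicate, pd.DataFrame):
        return per_replicate
    rows = []
    for i, item in enumerate(per_replicate):
        if isinstance(item, EquilibriumSummary):
            rows.append(
                {
                    "replicate": i,
                    "party": item.party_index,
                    "mean_distance": item.mean_distance,
                    "mean_fitness": item.mean_fitness,
                    "fixation_fraction": item.fixation_fraction,
                    "mean_fixation_size": item.mean_fixation_size,
                    "mean_lag_load": item.mean_lag_load,
                    "power_party1": math.nan,
                }
            )
        elif isinstance(item, PowerResult):
            rows.append({"replicate": i, "party": 1, "power_party1": item.power_party1})
        else:
            raise TypeError(f"cannot aggregate item of type {type(item).__name__}")
    return pd.DataFrame(rows)


def aggregate_replicates(per_replicate) -> pd.DataFrame:
    """Aggregate per-replicate statistics into a long table of means and SEs.

    Accepts the ``per_replicate`` data frame of
    :class:`~fgmconflict.simulate.ReplicateResults` (one row per replicate
    and party) or a flat list of :class:`EquilibriumSummary` /
    :class:`PowerResult` objects.  Returns a long-format frame with columns
    ``party, statistic, mean, se, n_replicates``.  Missing values (e.g.
    fixation size in replicates without fixations, power in single-party
    runs) are excluded; a statistic missing everywhere is reported with NaN
    mean.  The SE is the standard error of the replicate mean (ddof=1), NaN
    for a single replicate.
    """
    frame = _as_frame(per_replicate)
    if len(frame) == 0:
        raise ValueError("no replicates to aggregate")
    out = []
    for party, grp in frame.groupby("party"):
        for stat in SUMMARY_FIELDS:
            if stat not in grp.columns:
                continue
            if stat == "power_party1" and party != 1:
                continue
            vals = grp[stat].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            mean = float(np.mean(vals)) if n else math.nan
            se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            out.append(
                {"party": party, "statistic": stat, "mean": mean, "se": se, "n_replicates": n}
            )
    return pd.DataFrame(out)
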