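"""Diagnostics comparing the original ranking with the bootstrap-aggregated one.

The central quantity is the per-set rank difference

    gain = original_rank - bootstrap_rank

(positive: the set gained evidence under bootstrap aggregation, negative:
it lost, zero: retained). Sets in the extreme tails of the gain
distribution — below the 2.5% or above the 97.5% quantile by default —
changed rank so much between analyses that they should be treated as
unreliable for biological interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GainCounts",
    "RobustnessReport",
    "compare_ranks",
    "rank_diff_quantiles",
    "classify_gains",
    "cross_dataset_overlap",
]

DEFAULT_LOWER_Q = 0.025
DEFAULT_UPPER_Q = 0.975

FLAG_OK = "ok"
FLAG_EXTREME_LOSS = "extreme_loss"
FLAG_EXTREME_GAIN = "extreme_gain"


class GainCounts(NamedTuple):
    gain: int
    loss: int
    retained: int


@dataclass
class RobustnessReport:
    """Per-set gains plus the quantile thresholds used to flag extremes.

    ``table`` has columns set_id, original_rank, bootstrap_rank, gain, flag;
    ``only_original`` / ``only_bootstrap`` list sets found in just one
    ranking (they get no gain).
    """

    table: pd.DataFrame
    q_low: float
    q_high: float
    counts: GainCounts
    only_original: list[str]
    only_bootstrap: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q_low": [self.q_low],
                "q_high": [self.q_high],
                "n_gain": [self.counts.gain],
                "n_loss": [self.counts.loss],
                "n_retained": [self.counts.retained],
                "n_only_original": [len(self.only_original)],
                "n_only_bootstrap": [len(self.only_bootstrap)],
            }
        )


def _rank_map(ranking: pd.DataFrame) -> pd.Series:
    """Extract set_id -> rank from either an enrichment or aggregated table."""
    for col in ("rank", "aggregated_rank", "integrated_rank", "bootstrap_rank"):
        if col in ranking.columns:
            return ranking.set_index("set_id")[col]
    raise ValueError(f"no rank column found among {list(ranking.columns)}")


def compare_ranks(
    original: pd.DataFrame,
    aggregated: pd.DataFrame,
    lower: float = DEFAULT_LOWER_Q,
    upper: float = DEFAULT_UPPER_Q,
) -> RobustnessReport:
    """Per-set gain = original rank - bootstrap rank, with extreme-gain flags.

    Gains are computed on the intersection of the two vocabularies; an empty
    intersection is an error. Quantile flagging is skipped (all ``ok``) when
    fewer than two gains are available.
    """
    orig = _rank_map(original)
    boot = _rank_map(aggregated)
    common = [i for i in orig.index if i in boot.index]
    if not common:
        raise ValueError("the two rankings share no sets")
    gains = (orig.loc[common] - boot.loc[common]).to_numpy(dtype=float)
    if len(gains) >= 2:
        q_low, q_high, flags = rank_diff_quantiles(gains, lower, upper)
    else:
        q_low = q_high = float(gains[0])
        flags = np.array([FLAG_OK])
    table = pd.DataFrame(
        {
            "set_id": common,
            "original_rank": orig.loc[common].to_numpy(dtype=float),
            "bootstrap_rank": boot.loc[common].to_numpy(dtype=float),
            "gain": gains,
            "flag": flags,
        }
    )
    return RobustnessReport(
        table=table,
        q_low=q_low,
        q_high=q_high,
        counts=classify_gains(gains),
        only_original=[i for i in orig.index if i not in boot.index],
        only_bootstrap=[i for i in boot.index if i not in orig.index],
    )


def rank_diff_quantiles(
    gains: Sequence[float],
    lower: float = DEFAULT_LOWER_Q,
    upper: float = DEFAULT_UPPER_Q,
) -> tuple[float, float, np.ndarray]:
    """Linear-interpolation quantiles of the gain distribution plus flags.

    Sets strictly below the lower quantile are flagged ``extreme_loss``,
    strictly above the upper quantile ``extreme_gain``.
    """
    gains = np.asarray(gains, dtype=float)
    if gains.size < 2:
        raise ValueError("need at least two gains for quantile flagging")
    if not 0 < lower < upper < 1:
        raise ValueError(f"require 0 < lower < upper < 1, got ({lower}, {upper})")
    q_low, q_high = np.quantile(gains, [lower, upper], method="linear")
    flags = np.full(gains.shape, FLAG_OK, dtype=object)
    flags[gains < q_low] = FLAG_EXTREME_LOSS
    flags[gains > q_high] = FLAG_EXTREME_GAIN
    return float(q_low), float(q_high), flags


def classify_gains(gains: Iterable[float]) -> GainCounts:
    """Partition gains by sign; retained means an exact tie-averaged-rank match."""
    gains = np.asarray(list(gains), dtype=float)
    return GainCounts(
        gain=int((gains > 0).sum()),
        loss=int((gains < 0).sum()),
        retained=int((gains == 0).sum()),
    )


def cross_dataset_overlap(
    rankings: Sequence[pd.DataFrame],
    top_k: int,
    names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Which sets recur among the top_k of several independent rankings.

    Returns a boolean membership table (sets x datasets, restricted to sets
    in at least one top list) and a Series counting, for each m >= 2, the
    sets shared by at least m datasets. Works on original (Fisher-ordered)
    and aggregated (rho-ordered) tables alike.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    names = list(names) if names is not None else [f"dataset_{i}" for i in range(len(rankings))]
    tops = []
    for ranking in rankings:
        ranks = _rank_map(ranking)
        tops.append(frozenset(ranks[ranks <= top_k].index))
    all_ids = sorted(set().union(*tops))
    table = pd.DataFrame(
        {name: [i in top for i in all_ids] for name, top in zip(names, tops)},
        index=pd.Index(all_ids, name="set_id"),
    )
    presence = table.sum(axis=1)
    shared = pd.Series(
        {m: int((presence >= m).sum()) for m in range(2, len(rankings) + 1)},
        name="n_sets_shared_by_at_least",
    )
    return table, shared
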