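"""Integration of enrichment rankings across omics levels or studies.

Levels (e.g. transcriptomics and proteomics, or independent studies of the
same design) are each summarised by their bootstrap-aggregated ranking.
Integration restricts every level to the common set vocabulary, re-ranks
within it — levels annotate different numbers of sets, so raw list
positions are not comparable — normalises by the common-vocabulary size
and combines the per-level normalised ranks with the same
uniform-order-statistic score used for bootstrap aggregation, with m equal
to the number of levels. A set earns a small integrated score only when it
ranks high on every level.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import _rho_matrix
from .enrichment import round_significant

__all__ = ["VennCounts", "intersect_rankings", "integrate", "kendall_concordance"]



class VennCounts(NamedTuple):
    common: int
    exclusive: tuple[int, ...]  # one entry per level, in input order


def _vocabulary(ranking: pd.DataFrame) -> list[str]:
    return list(ranking["set_id"])


def intersect_rankings(levels: Sequence[pd.DataFrame]) -> tuple[list[str], VennCounts]:
    """Common set vocabulary across levels plus per-level exclusive counts.

    The common vocabulary keeps the first level's order. An empty
    intersection is an error.
    """
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    vocabularies = [set(_vocabulary(lv)) for lv in levels]
    common_set = set.intersection(*vocabularies)
    if not common_set:
        raise ValueError("levels share no sets")
    common = [s for s in _vocabulary(levels[0]) if s in common_set]
    exclusive = tuple(len(v - common_set) for v in vocabularies)
    return common, VennCounts(common=len(common), exclusive=exclusive)


def integrate(
    levels: Sequence[pd.DataFrame],
    common: Sequence[str] | None = None,
    level_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-level rankings into an integrated score and rank.

    ``levels`` are aggregated-ranking tables (columns ``set_id``,
    ``rho_score``, ``aggregated_rank``, optionally ``original_rank``).
    Each level is restricted to the common vocabulary and re-ranked there
    by ascending rho (tie-averaged); the integrated score is the
    order-statistic rho over the per-level normalised ranks. Per-level
    original/bootstrap ranks and gains are carried as provenance columns
    when available. The result is invariant under permutation of levels up
    to column naming.
    """
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    if common is None:
        common, _ = intersect_rankings(levels)
    common = list(common)
    if not common:
        raise ValueError("common vocabulary is empty")
    if level_names is None:
        level_names = [f"level{i + 1}" for i in range(len(levels))]

    n = len(common)
    normalized = np.empty((n, len(levels)))
    out = pd.DataFrame({"set_id": common})
    for j, (level, name) in enumerate(zip(levels, level_names)):
        lv = level.set_index("set_id").loc[common]
        score_col = "rho_score" if "rho_score" in lv.columns else None
        if score_col is not None:
            scores = lv[score_col].to_numpy(dtype=float)
        else:
            # fall back to ranking by whatever rank column the table carries
            rank_col = "aggregated_rank" if "aggregated_rank" in lv.columns else "rank"
            scores = lv[rank_col].to_numpy(dtype=float)
        reranked = stats.rankdata(round_significant(scores), method="average")
        normalized[:, j] = reranked / n
        out[f"bootstrap_rank_{name}"] = reranked
        if "original_rank" in lv.columns:
            out[f"original_rank_{name}"] = lv["original_rank"].to_numpy(dtype=float)
            out[f"gain_{name}"] = out[f"original_rank_{name}"] - out[f"bootstrap_rank_{name}"]

    out["integrated_score"] = _rho_matrix(normalized)
    out["integrated_rank"] = stats.rankdata(
        round_significant(out["integrated_score"].to_numpy()), method="average"
    )
    return out.sort_values("integrated_rank", kind="stable").reset_index(drop=True)


def kendall_concordance(rank_list_a: pd.Series | dict, rank_list_b: pd.Series | dict) -> float:
    """Kendall tau-b (tie-corrected) between two rankings on their common sets."""
    a = pd.Series(rank_list_a)
    b = pd.Series(rank_list_b)
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need at least two common sets")
    tau = stats.kendalltau(a.loc[common], b.loc[common]).statistic
    return float(tau)
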