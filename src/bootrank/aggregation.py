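"""Robust rank aggregation of bootstrap replicate rankings.

The aggregation score follows the uniform-order-statistic approach of
Kolde et al.'s RobustRankAggreg: normalise each replicate's ranks to
(0, 1], sort a set's m normalised ranks, and take

    rho = min_k P(U_(k) <= r_(k)),   U_1..U_m iid Uniform(0, 1),

where ``P(U_(k) <= r)`` is the Beta(k, m-k+1) CDF, equivalently the
binomial upper tail ``sum_{j>=k} C(m,j) r^j (1-r)^(m-j)``. A small rho
means the set sits consistently near the top of the replicate rankings;
a set absent from a replicate contributes the worst possible normalised
rank 1.0, which is how survival across replicates enters the score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .bootstrap import BootstrapRankMatrix
from .enrichment import round_significant

__all__ = [
    "normalize_ranks",
    "beta_order_stat_p",
    "rho_score",
    "aggregate",
    "AGGREGATION_COLUMNS",
]

AGGREGATION_COLUMNS = (
    "set_id",
    "rho_score",
    "aggregated_rank",
    "n_occurrences",
    "original_rank",
    "original_p",
)



def normalize_ranks(matrix: BootstrapRankMatrix) -> pd.DataFrame:
    """Divide each replicate's ranks by its list length; missing -> 1.0."""
    lengths = np.asarray(matrix.list_lengths, dtype=float)
    normalized = matrix.ranks.to_numpy(dtype=float) / lengths[np.newaxis, :]
    normalized = np.where(np.isnan(normalized), 1.0, normalized)
    return pd.DataFrame(normalized, index=matrix.ranks.index, columns=matrix.ranks.columns)


def beta_order_stat_p(k: int, m: int, r: float) -> float:
    """P(U_(k) <= r) for the k-th smallest of m iid Uniform(0,1) variables."""
    if not 1 <= k <= m:
        raise ValueError(f"k must satisfy 1 <= k <= m, got k={k}, m={m}")
    if not 0 <= r <= 1:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    return float(special.betainc(k, m - k + 1, r))


def _rho_matrix(normalized: np.ndarray, correct: bool = False) -> np.ndarray:
    """Row-wise rho for a (sets x m) matrix of normalised ranks."""
    m = normalized.shape[1]
    srt = np.sort(normalized, axis=1)
    ks = np.arange(1, m + 1)
    tails = special.betainc(ks[np.newaxis, :], (m - ks + 1)[np.newaxis, :], srt)
    rho = tails.min(axis=1)
    if correct:
        rho = np.minimum(rho * m, 1.0)
    return rho


def rho_score(normalized_ranks, correct: bool = False) -> float:
    """Aggregation score of one set from its m normalised replicate ranks.

    ``correct=True`` applies the conservative Bonferroni-style ``min(m*rho, 1)``
    adjustment for the minimum over k; the default reports the raw minimum,
    which is sufficient when the score is only transformed into a rank.
    """
    r = np.asarray(list(normalized_ranks), dtype=float)
    if r.size == 0:
        raise ValueError("need at least one normalised rank")
    if ((r <= 0) | (r > 1)).any():
        raise ValueError("normalised ranks must lie in (0, 1]")
    return float(_rho_matrix(r[np.newaxis, :], correct=correct)[0])


def aggregate(
    matrix: BootstrapRankMatrix,
    original: pd.DataFrame,
    correct: bool = False,
) -> pd.DataFrame:
    """Collapse a bootstrap rank matrix into one aggregated ranking.

    ``original`` is the enrichment ranking of the unperturbed analysis (the
    `ora_fisher` table); its rank and p-value are carried along so that the
    aggregated and original rankings can be compared set by set. The
    vocabulary is the union: sets absent from the matrix (never surviving a
    replicate) score rho = 1, sets absent from the original analysis carry
    NaN original rank.

    Returns a DataFrame with :data:`AGGREGATION_COLUMNS`, sorted by
    ascending aggregated rank.
    """
    orig = original.set_index("set_id")
    all_ids = list(matrix.ranks.index) + [i for i in orig.index if i not in matrix.ranks.index]
    normalized = normalize_ranks(matrix).reindex(all_ids).fillna(1.0)
    occurrences = matrix.ranks.reindex(all_ids).notna().sum(axis=1)

    rho = _rho_matrix(normalized.to_numpy(), correct=correct)
    out = pd.DataFrame(
        {
            "set_id": all_ids,
            "rho_score": rho,
            "aggregated_rank": stats.rankdata(round_significant(rho), method="average"),
            "n_occurrences": occurrences.to_numpy(),
            "original_rank": orig["rank"].reindex(all_ids).to_numpy(),
            "original_p": orig["p_fisher"].reindex(all_ids).to_numpy(),
        }
    )
    return out.sort_values("aggregated_rank", kind="stable").reset_index(drop=True)
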