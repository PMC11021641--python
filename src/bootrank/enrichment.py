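"""Over-representation scoring of gene sets and tie-averaged ranking.

The built-in scorer is the one-sided hypergeometric test (Fisher's exact
test on the 2x2 table in-set x differentially-expressed, upper tail): for a
set with ``n`` members in a universe of ``N`` features of which ``K`` are
selected as differentially expressed, the enrichment p-value of an observed
overlap ``k`` is ``P(X >= k)`` with ``X ~ Hypergeometric(N, K, n)``.

Rankings are by ascending p-value with mean ranks for ties, so the rank
column of an N-set table always sums to N(N+1)/2.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .gene_set_io import DEResult, GeneSetCollection

__all__ = [
    "select_de_features",
    "hypergeom_tail",
    "ora_fisher",
    "rank_by_pvalue",
    "RANKING_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Column contract of an enrichment ranking table.
RANKING_COLUMNS = ("set_id", "description", "set_size", "overlap", "p_fisher", "rank")

#: Mantissa bits kept when comparing scores for ties before rank-averaging:
#: values agreeing to ~1e-12 relative precision are treated as equal. The
#: rounding is relative, not absolute — enrichment p-values span hundreds of
#: orders of magnitude and must not be collapsed towards zero.
_TIE_MANTISSA_BITS = 40


def round_significant(values, bits: int = _TIE_MANTISSA_BITS) -> np.ndarray:
    """Round to ``bits`` mantissa bits (relative rounding; overflow-free)."""
    mantissa, exponent = np.frexp(np.asarray(values, dtype=float))
    scale = float(1 << bits)
    return np.ldexp(np.round(mantissa * scale) / scale, exponent)


def select_de_features(
    de: DEResult,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
    use_adjusted: bool = True,
) -> frozenset[str]:
    """Select differentially expressed features by p-value and fold-change.

    A feature is selected when its (adjusted, by default) p-value is below
    ``p_threshold`` and ``|logfc|`` exceeds ``lfc_threshold`` (0 disables the
    fold-change filter). An empty selection is legal — downstream enrichment
    p-values all become 1 — but is logged as a warning.
    """
    if p_threshold < 0:
        raise ValueError("p_threshold must be non-negative")
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be non-negative")
    if len(de) == 0:
        raise ValueError("DE table is empty")
    tab = de.table
    pcol = tab["p_adj"] if use_adjusted else tab["p"]
    mask = (pcol < p_threshold) & (tab["logfc"].abs() > lfc_threshold)
    selected = frozenset(tab.loc[mask, "feature_id"])
    if not selected:
        logger.warning(
            "DE selection is empty (p<%g on %s, |logfc|>%g); all enrichment "
            "p-values will be 1",
            p_threshold,
            "p_adj" if use_adjusted else "p",
            lfc_threshold,
        )
    return selected


def hypergeom_tail(k, N, K, n):
    """Upper-tail hypergeometric probability P(X >= k), vectorised.

    Computed through the survival function in log-stable form; exact 1.0 is
    returned for k <= 0.
    """
    k = np.asarray(k)
    return stats.hypergeom.sf(k - 1, N, K, n)


def rank_by_pvalue(pvalues: Iterable[float]) -> np.ndarray:
    """Tie-averaged ascending ranks of p-values (1 = most enriched).

    Equal p-values share the mean of the rank positions they occupy; values
    are compared after rounding to 12 significant digits so that
    floating-point ties are averaged rather than ordered arbitrarily.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.rankdata(round_significant(p), method="average")


def ora_fisher(
    de_features: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Score every set by one-sided over-representation and rank the table.

    ``collection`` must already be filtered against ``universe`` (see
    :func:`bootrank.gene_set_io.filter_collection`); ``de_features`` must be
    a subset of the universe. Returns a DataFrame with the columns in
    :data:`RANKING_COLUMNS`, sorted by rank.
    """
    uni = frozenset(universe)
    de = frozenset(de_features)
    stray = de - uni
    if stray:
        raise ValueError(
            f"{len(stray)} DE feature(s) outside the universe, e.g. {sorted(stray)[:3]}"
        )
    N, K = len(uni), len(de)
    rows = []
    for gs in collection:
        if not gs.members <= uni:
            raise ValueError(f"set {gs.set_id!r} has members outside the universe")
        rows.append((gs.set_id, gs.description, len(gs.members), len(gs.members & de)))
    if not rows:
        return pd.DataFrame(columns=list(RANKING_COLUMNS))
    table = pd.DataFrame(rows, columns=["set_id", "description", "set_size", "overlap"])
    table["p_fisher"] = hypergeom_tail(
        table["overlap"].to_numpy(), N, K, table["set_size"].to_numpy()
    )
    table["rank"] = rank_by_pvalue(table["p_fisher"])
    return table.sort_values("rank", kind="stable").reset_index(drop=True)


#: A scorer maps (de_features, universe, collection) to a ranking table with
#: the :data:`RANKING_COLUMNS` contract. `ora_fisher` is the built-in one;
#: the bootstrap layer accepts any callable with this signature.
Scorer = Callable[[frozenset, frozenset, GeneSetCollection], pd.DataFrame]
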