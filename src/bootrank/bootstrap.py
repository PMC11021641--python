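"""Bootstrap engine: repeat enrichment on subsampled gene universes.

Each replicate draws a fixed fraction (default 95%) of the measured
universe without replacement, restricts the DE selection and every gene
set to that subsample, re-applies the size filters and re-ranks. The name
"bootstrap" is the field's usage for this procedure; the draws are
subsamples, not with-replacement resamples.

Replicate b uses a child generator seeded from ``(seed, b)``, so enlarging
B extends the matrix without reshuffling earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import Scorer, ora_fisher, select_de_features
from .gene_set_io import (
    DEFAULT_MAX_SIZE,
    DEFAULT_MIN_SIZE,
    DEResult,
    GeneSetCollection,
    filter_collection,
)

__all__ = ["EnrichmentConfig", "BootstrapRankMatrix", "draw_subsampled_universe", "run_bootstrap"]

DEFAULT_B = 100
DEFAULT_FRACTION = 0.95


@dataclass(frozen=True)
class EnrichmentConfig:
    """Thresholds shared by the original analysis and every replicate."""

    p_threshold: float = 0.05
    lfc_threshold: float = 0.0
    use_adjusted: bool = True
    min_size: int = DEFAULT_MIN_SIZE
    max_size: int = DEFAULT_MAX_SIZE


@dataclass
class BootstrapRankMatrix:
    """Sets x replicates matrix of tie-averaged ranks with explicit missingness.

    ``ranks`` is indexed by set_id with one column per replicate; entry
    (s, b) is NaN when set s was filtered out of replicate b (its subsampled
    size fell outside the size bounds). ``list_lengths[b]`` is the number of
    sets ranked in replicate b, so every column's non-missing ranks sum to
    L_b (L_b + 1) / 2.
    """

    ranks: pd.DataFrame
    list_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.list_lengths is None:
            self.list_lengths = self.ranks.notna().sum(axis=0).to_numpy()
        self.list_lengths = np.asarray(self.list_lengths)
        if len(self.list_lengths) != self.ranks.shape[1]:
            raise ValueError("one list length per replicate required")

    @property
    def n_replicates(self) -> int:
        return self.ranks.shape[1]

    @property
    def set_ids(self) -> list[str]:
        return list(self.ranks.index)

    def to_tsv(self, path) -> None:
        self.ranks.to_csv(path, sep="\t", na_rep="NA", index_label="set_id")

    @classmethod
    def from_tsv(cls, path) -> "BootstrapRankMatrix":
        ranks = pd.read_csv(path, sep="\t", index_col="set_id", na_values="NA")
        ranks.columns = [int(c) for c in ranks.columns]
        return cls(ranks)


def draw_subsampled_universe(
    universe, fraction: float, rng: np.random.Generator
) -> frozenset[str]:
    """Draw floor(fraction * N) distinct features uniformly without replacement."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    items = np.asarray(sorted(universe))
    size = int(np.floor(fraction * len(items)))
    return frozenset(rng.choice(items, size=size, replace=False))


def run_bootstrap(
    de: DEResult,
    collection: GeneSetCollection,
    B: int = DEFAULT_B,
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
    config: EnrichmentConfig | None = None,
    scorer: Scorer = ora_fisher,
) -> BootstrapRankMatrix:
    """Run B subsampled enrichment replicates and collect the rank matrix.

    ``collection`` should already be filtered against the full universe.
    The DE feature list is derived once from the full table and intersected
    with each subsample — the upstream differential-expression statistics do
    not change across replicates, only the universe does.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    config = config or EnrichmentConfig()
    if len(collection) == 0:
        raise ValueError("collection is empty after filtering")
    universe = de.universe
    selected = select_de_features(
        de, config.p_threshold, config.lfc_threshold, config.use_adjusted
    )
    columns: dict[int, pd.Series] = {}
    lengths = np.empty(B, dtype=int)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        sub = draw_subsampled_universe(universe, fraction, rng)
        sub_collection = filter_collection(collection, sub, config.min_size, config.max_size)
        if len(sub_collection) == 0:
            raise ValueError(f"replicate {b}: no set survived the size filters")
        ranking = scorer(selected & sub, sub, sub_collection)
        columns[b] = ranking.set_index("set_id")["rank"]
        lengths[b] = len(ranking)
    matrix = pd.DataFrame(columns).reindex(collection.set_ids)
    matrix = matrix.loc[matrix.notna().any(axis=1)]
    return BootstrapRankMatrix(matrix, lengths)
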