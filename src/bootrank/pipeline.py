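"""End-to-end composition: original enrichment + bootstrap + aggregation."""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

from .aggregation import aggregate
from .bootstrap import (
    DEFAULT_B,
    DEFAULT_FRACTION,
    BootstrapRankMatrix,
    EnrichmentConfig,
    run_bootstrap,
)
from .enrichment import ora_fisher, select_de_features
from .gene_set_io import DEResult, GeneSetCollection, filter_collection

__all__ = ["BootResult", "run_pipeline"]


class BootResult(NamedTuple):
    original: pd.DataFrame
    matrix: BootstrapRankMatrix
    aggregated: pd.DataFrame


def run_pipeline(
    de: DEResult,
    collection: GeneSetCollection,
    B: int = DEFAULT_B,
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
    config: EnrichmentConfig | None = None,
) -> BootResult:
    """Original analysis, B subsampled replicates, and the aggregated ranking.

    Filters the collection against the DE universe, scores the unperturbed
    analysis, runs the bootstrap and aggregates the replicate ranks into the
    rho-based ranking carrying the original ranks alongside.
    """
    config = config or EnrichmentConfig()
    universe = de.universe
    filtered = filter_collection(collection, universe, config.min_size, config.max_size)
    if len(filtered) == 0:
        raise ValueError("no gene set survives the universe/size filters")
    selected = select_de_features(
        de, config.p_threshold, config.lfc_threshold, config.use_adjusted
    )
    original = ora_fisher(selected, universe, filtered)
    matrix = run_bootstrap(de, filtered, B=B, fraction=fraction, seed=seed, config=config)
    aggregated = aggregate(matrix, original)
    return BootResult(original, matrix, aggregated)
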