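"""Synthetic DE tables and gene-set collections with planted enrichment.

The generator emulates the statistical structure the pipeline consumes: a
differential-expression table (uniform p-values under the null, Beta(a, 1)
with a < 1 under the alternative, Benjamini-Hochberg adjustment, a
two-component symmetric log-fold-change model) and a gene-set collection in
which three kinds of sets are planted:

* background sets — members drawn uniformly from the universe;
* robust sets — enrichment spread over many moderately significant
  members, so removing any handful of features barely moves the Fisher
  p-value;
* fragile sets — the enrichment signal carried by very few driver
  features, sized so that losing a single driver flips the set's Fisher
  decision at the configured thresholds. These are the sets the
  subsampling bootstrap is designed to expose.

Signal is injected at the p-value level rather than via expression
matrices: the pipeline's input contract is the DE result table, so
simulating counts would only exercise out-of-scope code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import hypergeom_tail, select_de_features
from .gene_set_io import DEResult, GeneSet, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "simulate_de",
    "simulate_collection",
    "simulate_paired_levels",
    "ROBUST_PREFIX",
    "FRAGILE_PREFIX",
    "SHARED_PREFIX",
    "SPECIFIC_PREFIX",
]

ROBUST_PREFIX = "ROBUST"
FRAGILE_PREFIX = "FRAGILE"
BACKGROUND_PREFIX = "BG"
SHARED_PREFIX = "SHARED"
SPECIFIC_PREFIX = "SPECIFIC"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a mid-sized expression study: 5,000 measured
    features of which 5% are truly differential, annotated by 200 gene
    sets of 10-80 members, with 10 robust and 10 fragile enriched sets
    planted among them.
    """

    n_features: int = 5000
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 80)
    pi0: float = 0.95  # null fraction of features
    beta_a: float = 0.15  # Beta(a, 1) shape of non-null p-values; a < 1
    n_robust: int = 10
    n_fragile: int = 10
    fragile_drivers: int = 2  # DE members carrying a fragile set's signal
    robust_size: int = 50
    robust_de_fraction: float = 0.5  # fraction of a robust set's members that are DE
    lfc_null_sd: float = 0.3
    lfc_alt_mean: float = 2.0
    lfc_alt_sd: float = 0.5
    # thresholds at which planted sets are calibrated (match pipeline defaults)
    p_threshold: float = 0.05
    lfc_threshold: float = 0.0
    use_adjusted: bool = True
    # multi-level layout
    n_shared_sets: int = 8
    n_specific_sets: int = 8  # per level
    n_exclusive_sets: int = 5  # vocabulary-only (background) sets unique to a level
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pi0 <= 1:
            raise ValueError("pi0 must lie in (0, 1]")
        if not 0 < self.beta_a < 1:
            raise ValueError("beta_a must lie in (0, 1)")
        if self.fragile_drivers < 1:
            raise ValueError("fragile_drivers must be >= 1")
        if self.set_size_range[0] < 1 or self.set_size_range[0] > self.set_size_range[1]:
            raise ValueError(f"bad set_size_range {self.set_size_range}")

    @classmethod
    def paired_default(cls) -> "SimulationConfig":
        """Smaller two-level layout used for cross-level integration studies."""
        return cls(n_features=2000, n_sets=60, n_robust=0, n_fragile=0)


def _feature_names(n: int) -> np.ndarray:
    return np.array([f"F{i:06d}" for i in range(n)])


def simulate_de(config: SimulationConfig, rng: np.random.Generator | None = None) -> DEResult:
    """Draw a DE table: uniform null p-values, Beta(a, 1) alternatives, BH adjustment.

    Non-null features are placed at random positions. Log fold changes come
    from a symmetric two-component model (tight around 0 for nulls, at
    +/- ``lfc_alt_mean`` for alternatives) so |logfc| thresholding is
    exercised. Deterministic given the config seed (or an explicit rng).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_features
    features = _feature_names(n)
    n_alt = int(round((1 - config.pi0) * n))
    alt_idx = rng.choice(n, size=n_alt, replace=False)
    is_alt = np.zeros(n, dtype=bool)
    is_alt[alt_idx] = True

    p = rng.uniform(size=n)
    if n_alt:
        p[is_alt] = rng.beta(config.beta_a, 1.0, size=n_alt)
    p_adj = multipletests(p, method="fdr_bh")[1]

    sign = rng.choice([-1.0, 1.0], size=n)
    logfc = sign * np.abs(rng.normal(0.0, config.lfc_null_sd, size=n))
    if n_alt:
        logfc[is_alt] = sign[is_alt] * np.abs(
            rng.normal(config.lfc_alt_mean, config.lfc_alt_sd, size=n_alt)
        )
    return DEResult(
        pd.DataFrame({"feature_id": features, "p": p, "p_adj": p_adj, "logfc": logfc})
    )


def _selected_features(config: SimulationConfig, de: DEResult) -> np.ndarray:
    sel = select_de_features(
        de, config.p_threshold, config.lfc_threshold, config.use_adjusted
    )
    return np.array(sorted(sel))


def _fragile_size(N: int, K: int, f: int, p_threshold: float, max_size: int = 400) -> int:
    """Largest set size such that f DE drivers are jointly significant but
    f - 1 drivers (after one is dropped from the universe) are not.

    Larger sets make each driver more load-bearing, so the largest
    qualifying size is the most fragile construction.
    """
    flipping, significant = [], []
    for size in range(f + 1, max_size + 1):
        p_full = float(hypergeom_tail(f, N, K, size))
        p_dropped = float(hypergeom_tail(f - 1, N - 1, K - 1, size - 1))
        if p_full < p_threshold:
            significant.append(size)
            if p_dropped >= p_threshold:
                flipping.append(size)
    if flipping:
        return max(flipping)
    if significant:
        return max(significant)
    raise ValueError(
        f"no fragile set size exists for {f} drivers with {K}/{N} DE features"
    )


def _sample_set(
    rng: np.random.Generator,
    size: int,
    n_signal: int,
    signal_pool: np.ndarray,
    null_pool: np.ndarray,
) -> frozenset[str]:
    n_signal = min(n_signal, len(signal_pool), size)
    chosen = list(rng.choice(signal_pool, size=n_signal, replace=False))
    chosen += list(rng.choice(null_pool, size=size - n_signal, replace=False))
    return frozenset(chosen)


def simulate_collection(
    config: SimulationConfig,
    de: DEResult,
    rng: np.random.Generator | None = None,
    signal_pools: dict[str, np.ndarray] | None = None,
) -> GeneSetCollection:
    """Build a collection of background, robust and fragile sets around ``de``.

    ``signal_pools`` optionally maps extra planted-set prefixes to feature
    pools (used by :func:`simulate_paired_levels` to plant shared and
    level-specific sets); each entry adds ``n_shared_sets`` /
    ``n_specific_sets`` robust-style sets drawing their signal members
    from that pool.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    features = _feature_names(config.n_features)
    selected = _selected_features(config, de)
    if len(selected) < config.fragile_drivers + 1:
        raise ValueError(
            f"only {len(selected)} features pass the DE thresholds; "
            "cannot plant enriched sets"
        )
    null_pool = np.array(sorted(set(features) - set(selected)))
    N, K = config.n_features, len(selected)
    lo, hi = config.set_size_range

    sets: list[GeneSet] = []
    for i in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(features, size=size, replace=False))
        sets.append(GeneSet(f"{BACKGROUND_PREFIX}{i:04d}", "background set", members))
    for i in range(config.n_robust):
        n_de = max(1, int(round(config.robust_de_fraction * config.robust_size)))
        members = _sample_set(rng, config.robust_size, n_de, selected, null_pool)
        sets.append(GeneSet(f"{ROBUST_PREFIX}{i:02d}", "planted robust set", members))
    if config.n_fragile:
        size = _fragile_size(N, K, config.fragile_drivers, config.p_threshold)
        for i in range(config.n_fragile):
            members = _sample_set(rng, size, config.fragile_drivers, selected, null_pool)
            sets.append(GeneSet(f"{FRAGILE_PREFIX}{i:02d}", "planted fragile set", members))
    for prefix, pool in (signal_pools or {}).items():
        count = config.n_shared_sets if prefix.startswith(SHARED_PREFIX) else config.n_specific_sets
        for i in range(count):
            n_de = max(1, int(round(config.robust_de_fraction * config.robust_size)))
            members = _sample_set(rng, config.robust_size, n_de, np.asarray(pool), null_pool)
            sets.append(GeneSet(f"{prefix}{i:02d}", f"planted {prefix.lower()} set", members))
    return GeneSetCollection.from_sets(sets)


def simulate_paired_levels(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[tuple[DEResult, GeneSetCollection], tuple[DEResult, GeneSetCollection]]:
    """Two omics levels with shared and level-specific planted signal.

    Both levels measure the same feature space but draw independent DE
    tables. Sets with the SHARED prefix are planted enriched in both
    levels (their members oversample each level's own DE features); sets
    with the SPECIFIC_A / SPECIFIC_B prefixes are enriched in exactly one
    level and carry background composition in the other. A few exclusive
    background sets per level make the vocabularies overlap only
    partially, exercising the intersection step.
    """
    config = config or SimulationConfig.paired_default()
    if seed is not None:
        config = replace(config, seed=seed)
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=4)

    de_a = simulate_de(config, np.random.default_rng(seeds[0]))
    de_b = simulate_de(config, np.random.default_rng(seeds[1]))
    sel_a = _selected_features(config, de_a)
    sel_b = _selected_features(config, de_b)

    coll_a = simulate_collection(
        config,
        de_a,
        np.random.default_rng(seeds[2]),
        signal_pools={
            f"{SHARED_PREFIX}_": sel_a,
            f"{SPECIFIC_PREFIX}_A_": sel_a,
            f"{SPECIFIC_PREFIX}_B_": np.array([]),  # background composition here
        },
    )
    coll_b = simulate_collection(
        config,
        de_b,
        np.random.default_rng(seeds[3]),
        signal_pools={
            f"{SHARED_PREFIX}_": sel_b,
            f"{SPECIFIC_PREFIX}_A_": np.array([]),
            f"{SPECIFIC_PREFIX}_B_": sel_b,
        },
    )

    def _with_exclusives(coll: GeneSetCollection, tag: str, rng: np.random.Generator):
        features = _feature_names(config.n_features)
        extra = []
        for i in range(config.n_exclusive_sets):
            size = int(rng.integers(*config.set_size_range) + 1)
            members = frozenset(rng.choice(features, size=size, replace=False))
            extra.append(GeneSet(f"EXCL_{tag}_{i:02d}", "level-exclusive set", members))
        return GeneSetCollection.from_sets(list(coll) + extra)

    coll_a = _with_exclusives(coll_a, "A", np.random.default_rng(seeds[2] + 1))
    coll_b = _with_exclusives(coll_b, "B", np.random.default_rng(seeds[3] + 1))
    return (de_a, coll_a), (de_b, coll_b)
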