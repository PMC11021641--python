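import numpy as np
import pandas as pd
import pytest

from bootrank import (
    BootstrapRankMatrix,
    EnrichmentConfig,
    draw_subsampled_universe,
    run_bootstrap,
)
from bootrank.gene_set_io import GeneSet, GeneSetCollection
from bootrank.simulate import SimulationConfig, simulate_collection, simulate_de

SMALL = SimulationConfig(n_features=400, n_sets=30, n_robust=2, n_fragile=2,
                         set_size_range=(8, 25), pi0=0.8, seed=7)


@pytest.fixture(scope="module")
def small_inputs():
    de = simulate_de(SMALL)
    collection = simulate_collection(SMALL, de)
    return de, collection


class TestDrawSubsampledUniverse:
    def test_draws_floor_fraction(self, rng):
        universe = {f"G{i}" for i in range(100)}
        sub = draw_subsampled_universe(universe, 0.95, rng)
        assert len(sub) == 95
        assert sub <= universe

    def test_fraction_one_is_identity(self, rng):
        universe = {f"G{i}" for i in range(37)}
        assert draw_subsampled_universe(universe, 1.0, rng) == universe

    def test_deterministic_given_seed(self):
        universe = {f"G{i}" for i in range(50)}
        a = draw_subsampled_universe(universe, 0.5, np.random.default_rng(3))
        b = draw_subsampled_universe(universe, 0.5, np.random.default_rng(3))
        assert a == b

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.01])
    def test_invalid_fraction(self, fraction, rng):
        with pytest.raises(ValueError):
            draw_subsampled_universe({"G1"}, fraction, rng)


class TestRunBootstrap:
    def test_shape_and_column_validity(self, small_inputs):
        de, collection = small_inputs
        from bootrank.gene_set_io import filter_collection
        filtered = filter_collection(collection, de.universe)
        matrix = run_bootstrap(de, filtered, B=12, fraction=0.9, seed=1)
        assert matrix.n_replicates == 12
        # every column is a valid tie-averaged ranking of its non-missing sets
        for b in range(12):
            col = matrix.ranks[b].dropna()
            L = matrix.list_lengths[b]
            assert len(col) == L
            assert col.sum() == pytest.approx(L * (L + 1) / 2)
            assert col.max() <= L

    def test_fraction_one_reproduces_original(self, small_inputs):
        de, collection = small_inputs
        from bootrank import ora_fisher, select_de_features
        from bootrank.gene_set_io import filter_collection
        filtered = filter_collection(collection, de.universe)
        original = ora_fisher(select_de_features(de), de.universe, filtered)
        matrix = run_bootstrap(de, filtered, B=4, fraction=1.0, seed=9)
        orig = original.set_index("set_id")["rank"]
        for b in range(4):
            pd.testing.assert_series_equal(
                matrix.ranks[b].sort_index(), orig.sort_index(),
                check_names=False)

    def test_bitwise_determinism(self, small_inputs):
        de, collection = small_inputs
        from bootrank.gene_set_io import filter_collection
        filtered = filter_collection(collection, de.universe)
        m1 = run_bootstrap(de, filtered, B=6, fraction=0.9, seed=5)
        m2 = run_bootstrap(de, filtered, B=6, fraction=0.9, seed=5)
        pd.testing.assert_frame_equal(m1.ranks, m2.ranks)

    def test_growing_b_extends_without_reshuffling(self, small_inputs):
        de, collection = small_inputs
        from bootrank.gene_set_io import filter_collection
        filtered = filter_collection(collection, de.universe)
        m_small = run_bootstrap(de, filtered, B=3, fraction=0.9, seed=5)
        m_big = run_bootstrap(de, filtered, B=6, fraction=0.9, seed=5)
        pd.testing.assert_frame_equal(
            m_small.ranks, m_big.ranks[[0, 1, 2]].loc[
                m_big.ranks[[0, 1, 2]].notna().any(axis=1)])

    def test_set_below_min_size_goes_missing(self):
        # one set sits exactly at min_size, so any subsample that removes one
        # of its members must mark it missing in that replicate
        universe = [f"G{i}" for i in range(20)]
        de = _de_from_universe(universe, de_ids=universe[:4])
        fragile = GeneSet("AT_MIN", "", frozenset(universe[:5]))
        big = GeneSet("BIG", "", frozenset(universe))
        coll = GeneSetCollection.from_sets([fragile, big])
        config = EnrichmentConfig(min_size=5, use_adjusted=False)
        matrix = run_bootstrap(de, coll, B=30, fraction=0.75, seed=2, config=config)
        missing = matrix.ranks.loc["AT_MIN"].isna()
        assert missing.any()
        assert matrix.ranks.loc["BIG"].notna().all()

    def test_invalid_b(self, small_inputs):
        de, collection = small_inputs
        with pytest.raises(ValueError):
            run_bootstrap(de, collection, B=0)

    def test_tsv_roundtrip(self, small_inputs, tmp_path):
        de, collection = small_inputs
        from bootrank.gene_set_io import filter_collection
        filtered = filter_collection(collection, de.universe)
        matrix = run_bootstrap(de, filtered, B=4, fraction=0.9, seed=3)
        path = tmp_path / "matrix.tsv"
        matrix.to_tsv(path)
        back = BootstrapRankMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(matrix.ranks, back.ranks)
        assert (matrix.list_lengths == back.list_lengths).all()


def _de_from_universe(universe, de_ids):
    import pandas as pd

    from bootrank import DEResult
    de_ids = set(de_ids)
    return DEResult(pd.DataFrame({
        "feature_id": list(universe),
        "p": [0.001 if f in de_ids else 0.9 for f in universe],
        "p_adj": [0.01 if f in de_ids else 0.95 for f in universe],
        "logfc": [2.0 if f in de_ids else 0.0 for f in universe],
    }))
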