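import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bootrank import (
    SimulationConfig,
    hypergeom_tail,
    select_de_features,
    simulate_collection,
    simulate_de,
    simulate_paired_levels,
)
from bootrank.simulate import FRAGILE_PREFIX, ROBUST_PREFIX, SHARED_PREFIX, SPECIFIC_PREFIX

SMALL = SimulationConfig(n_features=600, n_sets=20, n_robust=2, n_fragile=2,
                         pi0=0.85, set_size_range=(8, 30), seed=11)


class TestSimulateDe:
    def test_deterministic_per_seed(self):
        a = simulate_de(SMALL)
        b = simulate_de(SMALL)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_null_pvalues_uniform(self):
        config = SimulationConfig(n_features=10000, pi0=1.0, seed=5)
        de = simulate_de(config)
        stat = stats.kstest(de.table["p"], "uniform").statistic
        # critical value at alpha=0.01, n=1e4
        assert stat < 1.628 / np.sqrt(10000)

    def test_alternatives_concentrate_near_zero(self):
        sharp = SimulationConfig(n_features=4000, pi0=0.5, beta_a=0.05, seed=5)
        de = simulate_de(sharp)
        assert (de.table["p"] < 0.05).mean() > 0.4

    def test_bh_adjustment_properties(self):
        de = simulate_de(SMALL)
        tab = de.table.sort_values("p")
        assert (tab["p_adj"] >= tab["p"] - 1e-15).all()
        assert tab["p_adj"].is_monotonic_increasing

    def test_logfc_two_component(self):
        de = simulate_de(SimulationConfig(n_features=5000, pi0=0.5, seed=2))
        # roughly half the features carry a large fold change
        assert 0.3 < (de.table["logfc"].abs() > 1).mean() < 0.7


@pytest.fixture(scope="module")
def de_and_coll():
    de = simulate_de(SMALL)
    return de, simulate_collection(SMALL, de)


class TestSimulateCollection:
    def test_layout(self, de_and_coll):
        _, coll = de_and_coll
        ids = coll.set_ids
        assert sum(i.startswith(ROBUST_PREFIX) for i in ids) == 2
        assert sum(i.startswith(FRAGILE_PREFIX) for i in ids) == 2
        assert len(coll) == 24

    def test_robust_sets_strongly_enriched(self, de_and_coll):
        de, coll = de_and_coll
        sel = select_de_features(de, SMALL.p_threshold, SMALL.lfc_threshold,
                                 SMALL.use_adjusted)
        N, K = SMALL.n_features, len(sel)
        for i in coll.set_ids:
            if i.startswith(ROBUST_PREFIX):
                k = len(coll[i].members & sel)
                assert hypergeom_tail(k, N, K, len(coll[i])) < 1e-6

    def test_fragile_sets_flip_when_driver_removed(self, de_and_coll):
        de, coll = de_and_coll
        sel = select_de_features(de, SMALL.p_threshold, SMALL.lfc_threshold,
                                 SMALL.use_adjusted)
        N, K = SMALL.n_features, len(sel)
        for i in coll.set_ids:
            if not i.startswith(FRAGILE_PREFIX):
                continue
            members = coll[i].members
            k = len(members & sel)
            assert k == SMALL.fragile_drivers
            assert hypergeom_tail(k, N, K, len(members)) < SMALL.p_threshold
            # dropping one driver from the universe flips the decision
            flipped = hypergeom_tail(k - 1, N - 1, K - 1, len(members) - 1)
            assert flipped >= SMALL.p_threshold

    def test_background_overlap_near_expectation(self, de_and_coll):
        de, coll = de_and_coll
        sel = select_de_features(de, SMALL.p_threshold, SMALL.lfc_threshold,
                                 SMALL.use_adjusted)
        rate = len(sel) / SMALL.n_features
        overlaps = [len(coll[i].members & sel) / len(coll[i])
                    for i in coll.set_ids if i.startswith("BG")]
        assert np.mean(overlaps) == pytest.approx(rate, abs=0.08)

    def test_oversized_request_rejected(self):
        config = SimulationConfig(n_features=50, n_sets=1, n_robust=0, n_fragile=0,
                                  set_size_range=(60, 60), pi0=0.5, seed=1)
        de = simulate_de(config)
        with pytest.raises(ValueError):
            simulate_collection(config, de)


class TestSimulatePairedLevels:
    def test_planted_signal_lands_where_configured(self):
        enriched_both = 0
        specific_ok = 0
        n_seeds = 15
        for seed in range(n_seeds):
            (de_a, ca), (de_b, cb) = simulate_paired_levels(seed=seed)
            checks = []
            for de, coll in ((de_a, ca), (de_b, cb)):
                sel = select_de_features(de)
                N, K = len(de), len(sel)
                checks.append({
                    i: float(hypergeom_tail(len(coll[i].members & sel), N, K,
                                            len(coll[i])))
                    for i in coll.set_ids
                    if i.startswith((SHARED_PREFIX, SPECIFIC_PREFIX))})
            shared_ids = [i for i in checks[0] if i.startswith(SHARED_PREFIX)]
            if all(checks[0][i] < 0.05 and checks[1][i] < 0.05 for i in shared_ids):
                enriched_both += 1
            spec_a = [i for i in checks[0] if i.startswith(f"{SPECIFIC_PREFIX}_A")]
            if all(checks[0][i] < 0.05 for i in spec_a) and \
               np.median([checks[1][i] for i in spec_a]) > 0.05:
                specific_ok += 1
        assert enriched_both >= 0.9 * n_seeds
        assert specific_ok >= 0.9 * n_seeds

    def test_vocabularies_overlap_partially(self):
        (_, ca), (_, cb) = simulate_paired_levels(seed=3)
        a, b = set(ca.set_ids), set(cb.set_ids)
        assert a & b
        assert a - b and b - a
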