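import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cernet.dataio import GeneSetCollection
from cernet.enrichment import (
    RankedList,
    correlation_ranking,
    gsea_es,
    gsea_permutation,
    guilt_by_association,
    hypergeometric_ora,
    ora_batch,
)
from cernet.synthetic_data import SimulationConfig, simulate_cohort, simulate_gene_sets


def enumeration_ora_p(universe_size, set_size, query_size, observed):
    """Exhaustive oracle: fraction of all draws with overlap >= observed."""
    universe = list(range(universe_size))
    members = set(range(set_size))
    hits = total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(members & set(draw)) >= observed:
            hits += 1
    return hits / total


class TestHypergeometricOra:
    def test_perfect_overlap_exact_value(self):
        genes = [f"g{i}" for i in range(10)]
        r = hypergeometric_ora(genes[:5], genes[:5], genes)
        assert r.p == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        r = hypergeometric_ora(genes[:3], genes[5:8], genes)
        assert r.overlap == 0 and r.p == pytest.approx(1.0)

    def test_set_outside_universe(self):
        genes = [f"g{i}" for i in range(6)]
        r = hypergeometric_ora(genes[:3], ["x", "y"], genes)
        assert r.set_size_in_universe == 0 and r.p == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_ora([], ["a"], ["a"])
        with pytest.raises(ValueError):
            hypergeometric_ora(["a"], ["a"], [])

    @pytest.mark.parametrize("universe_size,set_size,query_size", [
        (8, 3, 4), (10, 5, 5), (12, 6, 3), (9, 2, 6)])
    def test_matches_exhaustive_enumeration(self, universe_size, set_size,
                                            query_size):
        genes = [f"g{i}" for i in range(universe_size)]
        members = genes[:set_size]
        # test every achievable overlap via rotated queries
        for shift in range(universe_size - query_size + 1):
            query = genes[shift:shift + query_size]
            r = hypergeometric_ora(query, members, genes)
            expected = enumeration_ora_p(universe_size, set_size, query_size,
                                         r.overlap)
            assert r.p == pytest.approx(expected, rel=1e-9)


class TestOraBatch:
    def test_single_set_adj_equals_raw(self):
        genes = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection({"S": ("d", genes[:5])})
        (r,) = ora_batch(genes[:5], coll, genes)
        assert r.adj_p == pytest.approx(r.p)

    def test_two_set_step_up_by_hand(self):
        # engineered p-values 1/252 (perfect overlap) and 1.0 (disjoint):
        # step-up gives 2/252 and 1.0
        genes = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection({"hit": ("d", genes[:5]),
                                  "miss": ("d", genes[5:10])})
        results = ora_batch(genes[:5], coll, genes)
        by_name = {r.set_name: r for r in results}
        assert by_name["hit"].adj_p == pytest.approx(2 / 252)
        assert by_name["miss"].adj_p == pytest.approx(1.0)
        assert [r.set_name for r in results] == ["hit", "miss"]  # p ascending

    def test_empty_collection(self):
        assert ora_batch(["g0"], GeneSetCollection({}), ["g0", "g1"]) == []


def ranked(scores):
    return RankedList.from_scores(scores)


class TestGseaEs:
    def test_unweighted_top_singleton(self):
        r = ranked({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        es, running, leading = gsea_es(r, {"a"}, weight_p=0.0)
        np.testing.assert_allclose(running, [1, 2 / 3, 1 / 3, 0], atol=1e-12)
        assert es == pytest.approx(1.0)
        assert leading == ["a"]

    def test_unweighted_bottom_singleton(self):
        r = ranked({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        es, running, leading = gsea_es(r, {"d"}, weight_p=0.0)
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1, 0], atol=1e-12)
        assert es == pytest.approx(-1.0)
        assert leading == ["d"]

    def test_weighted_worked_example(self):
        # scores [4,3,2,1], set = top two: increments 4/7 and 3/7
        r = ranked({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        es, running, leading = gsea_es(r, {"a", "b"}, weight_p=1.0)
        np.testing.assert_allclose(running, [4 / 7, 1.0, 0.5, 0.0], atol=1e-12)
        assert es == pytest.approx(1.0)
        assert leading == ["a", "b"]

    def test_no_members_in_list_rejected(self):
        r = ranked({"a": 1.0, "b": 0.5})
        with pytest.raises(ValueError):
            gsea_es(r, {"z"})

    @settings(deadline=None, max_examples=40)
    @given(st.integers(4, 30), st.integers(0, 2 ** 30))
    def test_bounds_and_unweighted_antisymmetry(self, n, seed):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(n)]
        r = ranked(dict(zip(ids, rng.normal(size=n))))
        k = int(rng.integers(1, n))
        members = set(rng.choice(ids, size=k, replace=False))
        es_s, run_s, _ = gsea_es(r, members, weight_p=0.0)
        assert abs(es_s) <= 1.0 + 1e-12
        complement = set(ids) - members
        es_c, run_c, _ = gsea_es(r, complement, weight_p=0.0)
        np.testing.assert_allclose(run_c, -run_s, atol=1e-9)
        assert es_c == pytest.approx(-es_s, abs=1e-9)

    def test_weighted_es_bounded(self, small_cohort):
        hub = small_cohort.truth.triads[0][1]
        r = correlation_ranking(
            small_cohort.mirna.values.loc[hub].to_numpy(), small_cohort.mrna)
        for k in (2, 5, 20):
            es, _, _ = gsea_es(r, set(r.ids[:k]), weight_p=1.0)
            assert abs(es) <= 1.0 + 1e-12


class TestGseaPermutation:
    def test_extreme_set_is_significant(self):
        ids = [f"g{i:03d}" for i in range(100)]
        r = ranked({g: 100.0 - i for i, g in enumerate(ids)})
        coll = GeneSetCollection({"top": ("d", ids[:50])})
        (res,) = gsea_permutation(r, coll, n_perm=1000, seed=5)
        assert res.nes > 1 and res.p <= 0.01

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(8)
        ids = [f"g{i}" for i in range(50)]
        r = ranked(dict(zip(ids, rng.normal(size=50))))
        coll = GeneSetCollection({"s1": ("d", ids[:10]), "s2": ("d", ids[10:25])})
        a = gsea_permutation(r, coll, n_perm=300, seed=42)
        b = gsea_permutation(r, coll, n_perm=300, seed=42)
        assert [(x.set_name, x.es, x.nes, x.p) for x in a] == \
               [(x.set_name, x.es, x.nes, x.p) for x in b]

    def test_small_sets_skipped(self):
        ids = [f"g{i}" for i in range(20)]
        r = ranked(dict(zip(ids, np.arange(20.0)[::-1])))
        coll = GeneSetCollection({"tiny": ("d", [ids[0]]),
                                  "ok": ("d", ids[:5])})
        out = gsea_permutation(r, coll, n_perm=200, seed=1)
        assert [x.set_name for x in out] == ["ok"]

    def test_null_p_values_approximately_uniform(self):
        """Random sets on shuffled scores: rejection rate near nominal."""
        n_sig = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            ids = [f"g{i}" for i in range(100)]
            r = ranked(dict(zip(ids, rng.normal(size=100))))
            members = list(rng.choice(ids, size=10, replace=False))
            coll = GeneSetCollection({"rand": ("d", members)})
            (res,) = gsea_permutation(r, coll, n_perm=500, seed=rep)
            n_sig += res.p < 0.05
        assert 0.0 <= n_sig / reps <= 0.15


class TestGuiltByAssociation:
    def test_planted_target_set_outranks_decoys(self, small_config):
        """The hub miRNA's planted target set scores a negative ES (its
        targets anticorrelate) and beats every decoy set on |NES| in most
        seeds."""
        from conftest import reseed

        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = reseed(small_config, seed)
            c = simulate_cohort(cfg)
            coll = simulate_gene_sets(c.truth, cfg, seed=seed + 1000)
            hub = c.truth.triads[0][1]
            res = guilt_by_association(hub, c.mirna, c.mrna, coll,
                                       n_perm=500, seed=seed)
            target = next(r for r in res if r.set_name == "triad_targets")
            max_decoy = max(abs(r.nes) for r in res
                            if r.set_name.startswith("decoy"))
            wins += (target.nes < 0 and abs(target.nes) > max_decoy)
        assert wins / n_seeds >= 0.8

    def test_mrna_hub_excluded_from_own_ranking(self, small_cohort):
        hub = small_cohort.mrna.feature_ids[0]
        r = correlation_ranking(
            small_cohort.mrna.values.loc[hub].to_numpy(),
            small_cohort.mrna, exclude=hub)
        assert hub not in r.ids
        assert len(r) == small_cohort.mrna.n_features - 1

    def test_constant_hub_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="constant"):
            correlation_ranking(np.full(small_cohort.mrna.n_samples, 5.0),
                                small_cohort.mrna)

    def test_unknown_hub_rejected(self, small_cohort):
        coll = GeneSetCollection({"s": ("d", small_cohort.mrna.feature_ids[:5])})
        with pytest.raises(ValueError, match="hub"):
            guilt_by_association("nope", small_cohort.mirna,
                                 small_cohort.mrna, coll, n_perm=100)
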