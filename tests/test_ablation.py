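from collections import Counter

import numpy as np
import pytest

from conftest import random_signed_network
from synbench.ablation import (AnnealSchedule, build_training_variant,
                               permute_edge_weights,
                               rewire_degree_preserving,
                               rewire_strength_preserving, shuffle_features)
from synbench.data_model import (CellLineSynergyNetwork, FeatureStore,
                                 build_cell_line_networks)
from synbench.splits import make_split


class TestShuffleFeatures:
    def store(self, n=6):
        return FeatureStore("f", "real_vector",
                            {f"d{i}": np.full(3, float(i)) for i in range(n)},
                            dimension=3)

    def test_payload_multiset_conserved(self):
        store = self.store()
        shuffled = shuffle_features(store, seed=1)
        assert set(shuffled.entities()) == set(store.entities())
        before = sorted(tuple(v) for v in store.payloads.values())
        after = sorted(tuple(v) for v in shuffled.payloads.values())
        assert before == after

    def test_single_entity_unchanged(self):
        store = self.store(n=1)
        shuffled = shuffle_features(store, seed=5)
        assert np.array_equal(shuffled["d0"], store["d0"])

    def test_seeded_repeatability_and_movement(self):
        store = self.store()
        a = shuffle_features(store, seed=9)
        b = shuffle_features(store, seed=9)
        assert all(np.array_equal(a[e], b[e]) for e in store.entities())
        moved = [any(not np.array_equal(shuffle_features(store, seed=s)[e],
                                        store[e])
                     for e in store.entities())
                 for s in range(10)]
        assert any(moved)

    def test_derangement_mode(self):
        store = self.store()
        der = shuffle_features(store, seed=2, derangement=True)
        assert all(not np.array_equal(der[e], store[e])
                   for e in store.entities())


class TestDegreePreserving:
    def test_path_has_no_valid_swap(self):
        net = CellLineSynergyNetwork("c", edges=[("a", "b", 1.0),
                                                 ("b", "c", 2.0)])
        res = rewire_degree_preserving(net, seed=0)
        assert res.network.pair_set() == net.pair_set()

    def test_two_disjoint_edges_enumeration(self):
        net = CellLineSynergyNetwork("c", edges=[("a", "b", 1.0),
                                                 ("c", "d", 2.0)])
        allowed = [{("a", "b"), ("c", "d")}, {("a", "d"), ("b", "c")},
                   {("a", "c"), ("b", "d")}]
        seen = set()
        for seed in range(20):
            res = rewire_degree_preserving(net, seed=seed)
            assert res.network.pair_set() in allowed
            assert sorted(res.network.degree().values()) == [1, 1, 1, 1]
            seen.add(frozenset(res.network.pair_set()))
        assert len(seen) > 1  # the randomization actually moves edges

    @pytest.mark.parametrize("seed", range(5))
    def test_per_sign_degrees_invariant_and_simple(self, seed):
        net = random_signed_network(seed)
        res = rewire_degree_preserving(net, seed=seed)
        for sign in (+1, -1):
            before = Counter()
            after = Counter()
            for u, v, _ in net.sign_subgraph(sign):
                before[u] += 1; before[v] += 1
            for u, v, _ in res.network.sign_subgraph(sign):
                after[u] += 1; after[v] += 1
            assert before == after
        pairs = [(u, v) for u, v, _ in res.network.edges]
        assert len(pairs) == len(set(pairs))  # simple graph

    def test_weight_multiset_per_sign_conserved(self):
        net = random_signed_network(3)
        res = rewire_degree_preserving(net, seed=1)
        for sign in (+1, -1):
            assert sorted(w for _, _, w in net.sign_subgraph(sign)) == \
                sorted(w for _, _, w in res.network.sign_subgraph(sign))


class TestStrengthPreserving:
    def test_single_edge_unchanged(self):
        net = CellLineSynergyNetwork("c", edges=[("a", "b", 2.5)])
        res = rewire_strength_preserving(net, seed=0)
        assert res.network == net
        assert res.objective_trace[-1] == 0.0

    def test_equal_weight_disjoint_edges_all_minima(self):
        net = CellLineSynergyNetwork("c", edges=[("a", "b", 3.0),
                                                 ("c", "d", 3.0)])
        res = rewire_strength_preserving(net, seed=4)
        # every degree-preserving rewiring preserves all strengths here
        assert res.objective_trace[-1] == pytest.approx(0.0, abs=1e-12)
        assert res.network.strength() == net.strength()

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_trace_monotone_and_degrees_kept(self, seed):
        net = random_signed_network(seed)
        res = rewire_strength_preserving(net, seed=seed)
        trace = res.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
        for sign in (+1, -1):
            before = Counter()
            after = Counter()
            for u, v, _ in net.sign_subgraph(sign):
                before[u] += 1; before[v] += 1
            for u, v, _ in res.network.sign_subgraph(sign):
                after[u] += 1; after[v] += 1
            assert before == after

    def test_reaches_small_relative_strength_error(self):
        net = random_signed_network(11, n_nodes=25)
        res = rewire_strength_preserving(net, seed=11)
        s_orig = net.strength()
        s_new = res.network.strength()
        num = sum((s_orig[v] - s_new[v]) ** 2 for v in net.nodes)
        den = sum(s ** 2 for s in s_orig.values())
        assert num / den < 0.01


class TestWeightPermutation:
    def test_edge_set_and_weight_multiset_conserved(self):
        net = random_signed_network(7)
        res = permute_edge_weights(net, seed=0)
        assert res.network.pair_set() == net.pair_set()
        assert sorted(w for _, _, w in res.network.edges) == \
            sorted(w for _, _, w in net.edges)
        assert res.retained_fraction == 1.0

    def test_seeded_determinism(self):
        net = CellLineSynergyNetwork("c", edges=[("a", "b", 1.0),
                                                 ("b", "c", 2.0),
                                                 ("a", "c", 3.0)])
        r1 = permute_edge_weights(net, seed=5)
        r2 = permute_edge_weights(net, seed=5)
        assert r1.network.edges == r2.network.edges


class TestTrainingVariants:
    def test_original_is_identity(self, random_table):
        split = make_split(random_table, "leave_drug_pair", seed=0)
        table, sp, stores = build_training_variant(random_table, split,
                                                   "original")
        assert table is random_table and sp is split

    def test_rewired_keeps_eval_partitions_original(self, random_table):
        split = make_split(random_table, "leave_drug_pair", seed=0)
        table, sp, _ = build_training_variant(
            random_table, split, "rewired", seed=1,
            rewire_method="weight_permutation")
        orig_test = sorted(random_table[i].key + (random_table[i].score,)
                           for i in split.test)
        new_test = sorted(table[i].key + (table[i].score,) for i in sp.test)
        assert new_test == orig_test
        orig_val = sorted(random_table[i].key for i in split.validation)
        assert sorted(table[i].key for i in sp.validation) == orig_val

    def test_ten_rewired_variants_share_test(self, random_table):
        split = make_split(random_table, "leave_drug_pair", seed=0)
        tests = set()
        for rep in range(10):
            table, sp, _ = build_training_variant(
                random_table, split, "rewired", seed=rep,
                rewire_method="degree_preserving")
            tests.add(tuple(sorted(table[i].key for i in sp.test)))
        assert len(tests) == 1

    def test_shuffled_variant_replaces_store(self, random_table):
        split = make_split(random_table, "leave_drug_pair", seed=0)
        store = FeatureStore("f", "real_vector",
                             {d: np.random.default_rng(1).normal(size=2)
                              for d in sorted(random_table.drug_universe)})
        _, _, stores = build_training_variant(
            random_table, split, "shuffled_features", seed=1,
            stores={"f": store}, shuffle_store="f")
        assert stores["f"] is not store
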