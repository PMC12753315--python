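import numpy as np
import pytest

from synbench import _nn
from synbench.data_model import FeatureStore, SynergyTriplet, TripletTable
from synbench.featurizers import smiles_to_graph
from synbench.models import (CHAR_VOCAB, GCNEncoder, ModelSpec,
                             TransformerEncoder, gcn_layer,
                             sinusoidal_positions, tokenize_smiles, train)
from synbench.splits import make_split


def brute_force_gcn(h, adj, w):
    """Dense textbook evaluation of sigma(D^-1/2 (A+I) D^-1/2 H W)."""
    a = adj + np.eye(adj.shape[0])
    d = np.diag(1.0 / np.sqrt(a.sum(axis=1)))
    return np.maximum(d @ a @ d @ h @ w, 0.0)


class TestGCNLayer:
    def test_single_node(self):
        h = np.array([[2.0, -1.0]])
        out = gcn_layer(h, np.zeros((1, 1)), np.eye(2))
        assert np.allclose(out, [[2.0, 0.0]])

    def test_two_nodes_average(self):
        # normalized augmented adjacency of a single edge is all-1/2
        h = np.array([[1.0], [3.0]])
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gcn_layer(h, adj, np.eye(1))
        assert np.allclose(out, [[2.0], [2.0]])

    def test_zero_features_linear(self):
        out = gcn_layer(np.zeros((3, 2)), np.zeros((3, 3)), np.eye(2),
                        activation=lambda x: x)
        assert np.allclose(out, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        adj = (rng.random((n, n)) < 0.5).astype(float)
        adj = np.triu(adj, 1); adj = adj + adj.T
        h = rng.normal(size=(n, 3))
        w = rng.normal(size=(3, 4))
        assert np.abs(gcn_layer(h, adj, w) - brute_force_gcn(h, adj, w)).max() < 1e-6


class TestGCNEncoder:
    def test_max_pool_definition(self):
        # single-atom graph: pooling is the identity on the one node vector
        g = smiles_to_graph("C")
        enc = GCNEncoder(g.atom_features.shape[1], 8, 2,
                         np.random.default_rng(0))
        emb = enc.encode(g)
        assert emb.data.shape == (8,)

    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        from synbench.featurizers import AtomFeaturedGraph
        feats = rng.normal(size=(5, 4))
        bonds = ((0, 1), (1, 2), (2, 3), (3, 4), (0, 4))
        g = AtomFeaturedGraph(feats, bonds)
        perm = np.array([4, 2, 0, 1, 3])
        inv = np.argsort(perm)
        g2 = AtomFeaturedGraph(feats[perm],
                               tuple(tuple(sorted((inv[i], inv[j])))
                                     for i, j in bonds))
        enc = GCNEncoder(4, 6, 2, np.random.default_rng(0))
        assert np.allclose(enc.encode(g).data, enc.encode(g2).data)


class TestTransformer:
    def test_tokenization_adds_specials(self):
        ids = tokenize_smiles("CCO")
        assert len(ids) == 5
        assert ids[0] == CHAR_VOCAB.index("[CLS]")
        assert ids[-1] == CHAR_VOCAB.index("[SEP]")

    def test_sinusoidal_row0_pattern(self):
        table = sinusoidal_positions(4, 6)
        assert np.allclose(table[0], [0, 1, 0, 1, 0, 1])

    @pytest.mark.parametrize("positional", ["sinusoidal", "learnable"])
    def test_deterministic_embedding(self, positional):
        kw = dict(vocab_size=len(CHAR_VOCAB), dim=8, n_layers=1, n_heads=2,
                  positional=positional)
        e1 = TransformerEncoder(rng=np.random.default_rng(5), **kw)
        e2 = TransformerEncoder(rng=np.random.default_rng(5), **kw)
        toks = [tokenize_smiles("CCO")]
        assert np.array_equal(e1.encode_batch(toks).data,
                              e2.encode_batch(toks).data)

    def test_padding_does_not_change_cls(self):
        enc = TransformerEncoder(len(CHAR_VOCAB), 8, 1, 2,
                                 np.random.default_rng(0))
        short = tokenize_smiles("CO")
        longer = tokenize_smiles("CCCCCCCC")
        alone = enc.encode_batch([short]).data[0]
        padded = enc.encode_batch([short, longer]).data[0]
        assert np.allclose(alone, padded, atol=1e-10)


class TestModelSpec:
    def test_preprocessor_xor_encoder(self):
        with pytest.raises(Exception, match="not both"):
            ModelSpec(drug_feature="MACCS", drug_preprocessor="ae",
                      drug_encoder="gcn")

    def test_label_naming(self):
        assert ModelSpec(drug_feature="smiles",
                         drug_encoder="transformer").label == "smiles (transformer)"
        assert ModelSpec(drug_feature="drug_one_hot").label == "drug_one_hot"


def small_training_setup(n_drugs=8, seed=0, noise=0.0):
    """Noise-free additive synthetic scores; learnable by the baseline."""
    rng = np.random.default_rng(seed)
    drugs = [f"d{i}" for i in range(n_drugs)]
    effect = rng.normal(0, 5, size=n_drugs)
    triplets = []
    for c in ("c1", "c2"):
        for i in range(n_drugs):
            for j in range(i + 1, n_drugs):
                triplets.append(SynergyTriplet.make(
                    drugs[i], drugs[j], c,
                    float(effect[i] + effect[j] + rng.normal(0, noise))))
    table = TripletTable(triplets)
    from synbench.featurizers import one_hot_features
    stores = {"drug_one_hot": one_hot_features(drugs, "drug_one_hot"),
              "cell_one_hot": one_hot_features(["c1", "c2"], "cell_one_hot")}
    return table, stores


class TestTraining:
    def test_overfits_noise_free_additive_data(self):
        table, stores = small_training_setup()
        split = make_split(table, "leave_triplet", seed=0)
        spec = ModelSpec(drug_feature="drug_one_hot", epochs=300,
                         learning_rate=3e-3, hidden_layers=(32, 16), seed=0)
        fitted = train(spec, table, split, stores)
        train_preds = fitted.predict_table(table, split.train)
        y = np.array([table[i].score for i in split.train])
        assert np.sqrt(np.mean((train_preds - y) ** 2)) < 1.0

    def test_seed_determinism(self):
        table, stores = small_training_setup()
        split = make_split(table, "leave_triplet", seed=0)
        spec = ModelSpec(drug_feature="drug_one_hot", epochs=5, seed=3)
        m1 = train(spec, table, split, stores)
        m2 = train(spec, table, split, stores)
        assert m1.validation_trace == m2.validation_trace

    def test_training_loss_decreases(self):
        table, stores = small_training_setup()
        split = make_split(table, "leave_triplet", seed=0)
        spec = ModelSpec(drug_feature="drug_one_hot", epochs=50, seed=0)
        fitted = train(spec, table, split, stores)
        assert min(fitted.training_trace) < fitted.training_trace[0]

    def test_pair_symmetry_under_augmented_training(self):
        table, stores = small_training_setup()
        split = make_split(table, "leave_triplet", seed=0)
        spec = ModelSpec(drug_feature="drug_one_hot", epochs=30, seed=0)
        fitted = train(spec, table, split, stores)
        t = table[split.test[0]]
        fwd = fitted.predict([(t.drug_a, t.drug_b, t.cell_line)])[0]
        rev = fitted.predict([(t.drug_b, t.drug_a, t.cell_line)])[0]
        # augmentation makes the order-sensitive decoder order-robust
        assert abs(fwd - rev) < 1.5

    def test_gcn_and_transformer_specs_train(self):
        rng = np.random.default_rng(0)
        smiles = {f"d{i}": s for i, s in enumerate(
            ["CCO", "CCN", "CCC", "c1ccccc1", "CC(=O)O", "CCOC"])}
        drugs = sorted(smiles)
        triplets = [SynergyTriplet.make(a, b, "c1", float(rng.normal()))
                    for i, a in enumerate(drugs) for b in drugs[i + 1:]]
        table = TripletTable(triplets)
        from synbench.featurizers import graph_store, one_hot_features, smiles_store
        stores = {"mol_graph": graph_store(smiles),
                  "smiles": smiles_store(smiles),
                  "cell_one_hot": one_hot_features(["c1"], "cell_one_hot")}
        split = make_split(table, "leave_triplet", seed=1)
        for feature, encoder in (("mol_graph", "gcn"), ("smiles", "transformer")):
            spec = ModelSpec(drug_feature=feature, drug_encoder=encoder,
                             epochs=3, encoder_dim=8, batch_size=8, seed=0)
            fitted = train(spec, table, split, stores)
            preds = fitted.predict_table(table, split.test)
            assert np.isfinite(preds).all()

    def test_test_scores_never_read(self):
        table, stores = small_training_setup()
        split = make_split(table, "leave_triplet", seed=0)
        spec = ModelSpec(drug_feature="drug_one_hot", epochs=2, seed=0)
        # train() asserts internally via the audited score wrapper; a clean
        # return certifies no test index was touched
        train(spec, table, split, stores)
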