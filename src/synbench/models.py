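"""Encoder–decoder synergy regression models.

A model is declared as feature x (optional preprocessor | optional
encoder) + MLP decoder:

- no encoder: the drug/cell feature vector feeds the decoder directly
  (this covers the one-hot baseline and every preprocessed-vector model);
- ``gcn``: graph convolutions over the atom-featured molecular graph with
  global max pooling, H' = sigma(D^-1/2 (A+I) D^-1/2 H W) per layer;
- ``transformer``: a small transformer encoder over tokenized SMILES
  ([CLS] + subwords + [SEP]); the final [CLS] representation is the drug
  embedding.  Positional encodings are sinusoidal or learnable.

The drug embeddings of the pair and the cell-line embedding are
concatenated and decoded by an MLP trained end-to-end under mean squared
error.  The checkpoint with the best validation MSE is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _nn
from ._nn import Tensor
from .data_model import FeatureStore, TripletTable, ValidationError
from .featurizers import AtomFeaturedGraph
from .splits import DataSplit

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "gcn_layer",
    "GCNEncoder",
    "TransformerEncoder",
    "tokenize_smiles",
    "sinusoidal_positions",
    "train",
    "AuditedScores",
    "CHAR_VOCAB",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model choice: feature (preprocessor | encoder) + decoder.

    ``drug_feature`` / ``cell_feature`` name entries of the feature-store
    mapping passed to :func:`train`.  A feature may have a preprocessor
    (already applied to its store) or a learnable encoder, not both.
    """

    drug_feature: str
    cell_feature: str = "cell_one_hot"
    drug_preprocessor: str | None = None
    drug_encoder: str | None = None  # None | "gcn" | "transformer"
    hidden_layers: tuple[int, ...] = (64, 32)
    dropout: float = 0.0
    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 128
    encoder_dim: int = 32
    encoder_layers: int = 2
    n_heads: int = 2
    positional_encoding: str = "sinusoidal"  # or "learnable"
    pair_augmentation: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.drug_preprocessor is not None and self.drug_encoder is not None:
            raise ValidationError(
                "a feature may use a preprocessor or an encoder, not both")
        if self.drug_encoder not in (None, "gcn", "transformer"):
            raise ValidationError(f"unknown encoder {self.drug_encoder!r}")

    @property
    def label(self) -> str:
        """Report label in the `feature (preprocessor, encoder)` style."""
        inner = ", ".join(x for x in (self.drug_preprocessor, self.drug_encoder) if x)
        return f"{self.drug_feature} ({inner})" if inner else self.drug_feature


# ---- GCN -----------------------------------------------------------------


def _normalized_adjacency(adj: np.ndarray) -> np.ndarray:
    """D^-1/2 (A + I) D^-1/2 with D the self-loop-augmented degree."""
    a_tilde = np.asarray(adj, dtype=float) + np.eye(adj.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(h: np.ndarray, adj: np.ndarray, weight: np.ndarray,
              activation=lambda x: np.maximum(x, 0.0)) -> np.ndarray:
    """One graph-convolution step sigma(D^-1/2 (A+I) D^-1/2 H W).

    Reference (non-learnable) evaluation used for oracle checks and
    inspection; the trainable path lives in :class:`GCNEncoder`.
    """
    if h.shape[0] != adj.shape[0]:
        raise ValidationError("node count mismatch between H and adjacency")
    if h.shape[1] != weight.shape[0]:
        raise ValidationError("feature dimension mismatch between H and W")
    if np.trace(adj) != 0:
        raise ValidationError("input adjacency must not contain self-loops")
    return activation(_normalized_adjacency(adj) @ h @ weight)


class GCNEncoder:
    """Stack of graph convolutions followed by global max pooling."""

    def __init__(self, in_dim: int, dim: int, n_layers: int,
                 rng: np.random.Generator):
        if n_layers < 1:
            raise ValidationError("GCN needs at least one layer")
        self.layers = [_nn.Linear(in_dim if i == 0 else dim, dim, rng)
                       for i in range(n_layers)]

    def encode(self, graph: AtomFeaturedGraph) -> Tensor:
        if graph.n_atoms == 0:
            raise ValidationError("cannot encode an empty graph")
        a_hat = Tensor(_normalized_adjacency(graph.adjacency()))
        h = Tensor(graph.atom_features)
        for lyr in self.layers:
            h = _nn.relu(a_hat @ lyr(h))
        return h.max_axis0()

    def parameters(self) -> list[Tensor]:
        return [p for lyr in self.layers for p in lyr.parameters()]


# ---- transformer ---------------------------------------------------------

CLS, SEP, PAD = "[CLS]", "[SEP]", "[PAD]"

#: character-level SMILES vocabulary for hermetic use; a byte-pair subword
#: vocabulary can be supplied as a file instead
CHAR_VOCAB = [PAD, CLS, SEP] + list(
    "#%()+-./0123456789=@ABCFHIKLMNOPRSTVXZ[\\]abcdefgilnoprstu")


def tokenize_smiles(smiles: str, vocab: Sequence[str] = CHAR_VOCAB,
                    fallback_char_split: bool = True) -> list[int]:
    """[CLS] + subword ids + [SEP].

    With the default character vocabulary each character is a token.  With
    a subword vocabulary, greedy longest-match is used; unknown spans fall
    back to character splitting when ``fallback_char_split`` (else raise).
    """
    index = {t: i for i, t in enumerate(vocab)}
    ids = [index[CLS]]
    i = 0
    while i < len(smiles):
        match = None
        for j in range(len(smiles), i, -1):
            if smiles[i:j] in index:
                match = smiles[i:j]
                break
        if match is None:
            if fallback_char_split and smiles[i] in index:
                match = smiles[i]
            else:
                raise ValidationError(
                    f"token at position {i} of {smiles!r} not in vocabulary")
        ids.append(index[match])
        i += len(match)
    ids.append(index[SEP])
    return ids


def sinusoidal_positions(n_positions: int, dim: int) -> np.ndarray:
    """Fixed sin/cos positional table; row 0 is (0, 1, 0, 1, ...)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10_000.0, 2 * i / dim)
    table = np.zeros((n_positions, dim))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


class TransformerEncoder:
    """Small pre-padding transformer over token sequences; returns the
    final-layer [CLS] representation."""

    MAX_LEN = 256

    def __init__(self, vocab_size: int, dim: int, n_layers: int, n_heads: int,
                 rng: np.random.Generator, positional: str = "sinusoidal"):
        if dim % n_heads:
            raise ValidationError("encoder_dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.embed = _nn.Embedding(vocab_size, dim, rng)
        self.positional = positional
        if positional == "learnable":
            self.pos = _nn.Embedding(self.MAX_LEN, dim, rng)
        elif positional == "sinusoidal":
            self.pos_table = sinusoidal_positions(self.MAX_LEN, dim)
        else:
            raise ValidationError(f"unknown positional encoding {positional!r}")
        self.blocks = []
        for _ in range(n_layers):
            blk = {
                "wq": _nn.Linear(dim, dim, rng), "wk": _nn.Linear(dim, dim, rng),
                "wv": _nn.Linear(dim, dim, rng), "wo": _nn.Linear(dim, dim, rng),
                "ff1": _nn.Linear(dim, 2 * dim, rng),
                "ff2": _nn.Linear(2 * dim, dim, rng),
                "ln1_g": Tensor(np.ones(dim), requires_grad=True),
                "ln1_b": Tensor(np.zeros(dim), requires_grad=True),
                "ln2_g": Tensor(np.ones(dim), requires_grad=True),
                "ln2_b": Tensor(np.zeros(dim), requires_grad=True),
            }
            self.blocks.append(blk)

    def encode_batch(self, token_ids: Sequence[Sequence[int]]) -> Tensor:
        """Encode a batch of variable-length sequences; (batch, dim) [CLS]."""
        b = len(token_ids)
        length = max(len(t) for t in token_ids)
        if length > self.MAX_LEN:
            raise ValidationError(f"sequence longer than {self.MAX_LEN} tokens")
        ids = np.zeros((b, length), dtype=np.int64)  # PAD = 0
        mask = np.full((b, 1, 1, length), -1e9)
        for r, toks in enumerate(token_ids):
            ids[r, :len(toks)] = toks
            mask[r, 0, 0, :len(toks)] = 0.0
        x = self.embed(ids.reshape(-1)).reshape(b, length, self.dim)
        if self.positional == "learnable":
            pos = self.pos(np.tile(np.arange(length), b)).reshape(b, length, self.dim)
            x = x + pos
        else:
            x = x + Tensor(self.pos_table[None, :length])
        h, dh = self.n_heads, self.dim // self.n_heads
        for blk in self.blocks:
            q = blk["wq"](x).reshape(b, length, h, dh).transpose((0, 2, 1, 3))
            k = blk["wk"](x).reshape(b, length, h, dh).transpose((0, 2, 1, 3))
            v = blk["wv"](x).reshape(b, length, h, dh).transpose((0, 2, 1, 3))
            scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(dh))
            attn = _nn.softmax(scores + Tensor(mask))
            ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, length, self.dim)
            x = _nn.layer_norm(x + blk["wo"](ctx), blk["ln1_g"], blk["ln1_b"])
            ff = blk["ff2"](_nn.relu(blk["ff1"](x)))
            x = _nn.layer_norm(x + ff, blk["ln2_g"], blk["ln2_b"])
        return x.slice_axis1(0)

    def parameters(self) -> list[Tensor]:
        ps = self.embed.parameters()
        if self.positional == "learnable":
            ps += self.pos.parameters()
        for blk in self.blocks:
            for key in ("wq", "wk", "wv", "wo", "ff1", "ff2"):
                ps += blk[key].parameters()
            ps += [blk["ln1_g"], blk["ln1_b"], blk["ln2_g"], blk["ln2_b"]]
        return ps


# ---- assembled model -----------------------------------------------------


class AuditedScores:
    """Score accessor that records every index read during training, so a
    run can prove it never touched test-set targets."""

    def __init__(self, table: TripletTable):
        self._scores = table.scores()
        self.accessed: set[int] = set()

    def take(self, indices: np.ndarray) -> np.ndarray:
        self.accessed.update(int(i) for i in np.asarray(indices).ravel())
        return self._scores[np.asarray(indices)]


class _Assembled:
    """Internal: the live parameterized model behind a TrainedModel."""

    def __init__(self, spec: ModelSpec, drug_store: FeatureStore,
                 cell_store: FeatureStore, rng: np.random.Generator):
        self.spec = spec
        self.drug_store = drug_store
        self.cell_store = cell_store
        if cell_store.dimension is None:
            raise ValidationError("cell feature must be a vector store")
        self.encoder = None
        if spec.drug_encoder is None:
            if drug_store.dimension is None:
                raise ValidationError(
                    f"feature {spec.drug_feature!r} is not a vector store; "
                    f"an encoder is required")
            drug_dim = drug_store.dimension
        elif spec.drug_encoder == "gcn":
            if drug_store.modality != "molecular_graph":
                raise ValidationError("gcn encoder needs a molecular_graph store")
            in_dim = next(iter(drug_store.payloads.values())).atom_features.shape[1]
            self.encoder = GCNEncoder(in_dim, spec.encoder_dim,
                                      spec.encoder_layers, rng)
            drug_dim = spec.encoder_dim
        else:  # transformer
            if drug_store.modality != "text":
                raise ValidationError("transformer encoder needs a text store")
            self.encoder = TransformerEncoder(
                len(CHAR_VOCAB), spec.encoder_dim, spec.encoder_layers,
                spec.n_heads, rng, positional=spec.positional_encoding)
            self._tokens = {d: tokenize_smiles(drug_store[d])
                            for d in drug_store.entities()}
            drug_dim = spec.encoder_dim
        self.decoder = _nn.MLP(2 * drug_dim + cell_store.dimension,
                               list(spec.hidden_layers), 1, rng,
                               dropout=spec.dropout)

    def parameters(self) -> list[Tensor]:
        ps = self.decoder.parameters()
        if self.encoder is not None:
            ps += self.encoder.parameters()
        return ps

    def _drug_embeddings(self, drugs: list[str]) -> dict[str, Tensor]:
        unique = sorted(set(drugs))
        if self.encoder is None:
            return {d: Tensor(np.asarray(self.drug_store[d], dtype=float)[None, :])
                    for d in unique}
        if isinstance(self.encoder, GCNEncoder):
            return {d: self.encoder.encode(self.drug_store[d]).reshape(1, -1)
                    for d in unique}
        embs = self.encoder.encode_batch([self._tokens[d] for d in unique])
        return {d: embs.take_rows(np.array([i])) for i, d in enumerate(unique)}

    def predict_batch(self, triples: list[tuple[str, str, str]],
                      train_mode: bool = False) -> Tensor:
        cells = Tensor(np.stack([np.asarray(self.cell_store[c], dtype=float)
                                 for _, _, c in triples]))
        if self.encoder is None:
            # features are constants here; stack them directly
            a = Tensor(np.stack([np.asarray(self.drug_store[a], dtype=float)
                                 for a, _, _ in triples]))
            b = Tensor(np.stack([np.asarray(self.drug_store[b], dtype=float)
                                 for _, b, _ in triples]))
            return self.decoder(_nn.concat([a, b, cells], axis=1),
                                train=train_mode)
        emb = self._drug_embeddings([d for a, b, _ in triples for d in (a, b)])
        rows_a = _nn.concat([emb[a] for a, _, _ in triples], axis=0) \
            if len(triples) > 1 else emb[triples[0][0]]
        rows_b = _nn.concat([emb[b] for _, b, _ in triples], axis=0) \
            if len(triples) > 1 else emb[triples[0][1]]
        x = _nn.concat([rows_a, rows_b, cells], axis=1)
        return self.decoder(x, train=train_mode)


@dataclass
class TrainedModel:
    """A fitted model: spec, learned parameter state, and loss traces."""

    spec: ModelSpec
    training_trace: list[float]
    validation_trace: list[float]
    _assembled: _Assembled = field(repr=False)
    _best_state: list[np.ndarray] = field(repr=False)

    def predict(self, triples: Sequence[tuple[str, str, str]]) -> np.ndarray:
        _nn.set_state(self._assembled.parameters(), self._best_state)
        preds = []
        for lo in range(0, len(triples), 512):
            chunk = list(triples[lo:lo + 512])
            preds.append(self._assembled.predict_batch(chunk).data[:, 0])
        return np.concatenate(preds)

    def predict_table(self, table: TripletTable,
                      indices: Sequence[int]) -> np.ndarray:
        return self.predict([table[i].key for i in indices])


def train(spec: ModelSpec, table: TripletTable, split: DataSplit,
          stores: Mapping[str, FeatureStore]) -> TrainedModel:
    """End-to-end training under MSE on the split's training partition.

    Validation MSE is evaluated each epoch and the best-validation
    checkpoint is returned.  Test indices are never read: scores are pulled
    through an access-audited wrapper and the audit is asserted before
    returning.  Deterministic given ``spec.seed``.
    """
    for part, idx in split.partitions().items():
        if not idx:
            raise ValidationError(f"partition {part!r} is empty")
    if spec.drug_feature not in stores or spec.cell_feature not in stores:
        raise ValidationError(
            f"stores must provide {spec.drug_feature!r} and {spec.cell_feature!r}")
    drug_store = stores[spec.drug_feature]
    cell_store = stores[spec.cell_feature]
    for part, idx in split.partitions().items():
        for i in idx:
            t = table[i]
            if spec.drug_encoder is None and (
                    t.drug_a not in drug_store or t.drug_b not in drug_store):
                raise ValidationError(f"{part}: drug of {t.key} missing from store")

    rng = np.random.default_rng(spec.seed)
    model = _Assembled(spec, drug_store, cell_store, rng)
    params = model.parameters()
    opt = _nn.Adam(params, lr=spec.learning_rate)
    scores = AuditedScores(table)

    train_items: list[tuple[tuple[str, str, str], int]] = []
    for i in split.train:
        t = table[i]
        train_items.append(((t.drug_a, t.drug_b, t.cell_line), i))
        if spec.pair_augmentation:
            train_items.append(((t.drug_b, t.drug_a, t.cell_line), i))
    val_keys = [table[i].key for i in split.validation]
    val_y = scores.take(np.array(split.validation))

    n = len(train_items)
    train_trace: list[float] = []
    val_trace: list[float] = []
    best_val = np.inf
    best_state = _nn.get_state(params)
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, spec.batch_size):
            batch = [train_items[j] for j in order[lo:lo + spec.batch_size]]
            keys = [k for k, _ in batch]
            y = scores.take(np.array([i for _, i in batch]))
            opt.zero_grad()
            pred = model.predict_batch(keys, train_mode=True)
            diff = pred - Tensor(y[:, None])
            loss = (diff * diff).mean()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        train_trace.append(epoch_loss / n)
        val_pred = model.predict_batch(val_keys).data[:, 0]
        val_mse = float(np.mean((val_pred - val_y) ** 2))
        val_trace.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_state = _nn.get_state(params)

    forbidden = scores.accessed & set(split.test)
    assert not forbidden, f"training read test indices {sorted(forbidden)[:5]}"
    return TrainedModel(spec=spec, training_trace=train_trace,
                        validation_trace=val_trace, _assembled=model,
                        _best_state=best_state)


def decode(emb_a: np.ndarray, emb_b: np.ndarray, emb_cell: np.ndarray,
           mlp: _nn.MLP) -> float:
    """Decode one concatenated (drug, drug, cell) embedding to a score."""
    x = Tensor(np.concatenate([emb_a, emb_b, emb_cell])[None, :])
    return float(mlp(x).data[0, 0])
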