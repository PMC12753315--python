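"""One-shot feature transforms applied before end-to-end training.

Two transforms are provided: random walk with restart (RWR) over a
protein–protein interaction (PPI) network, which smooths a drug's binary
target profile into a diffusion profile over the whole network, and an
autoencoder that compresses sparse binary features (fingerprints, one-hot,
target profiles) into a dense latent vector.  Precomputed embedding tables
(e.g. exported from pretrained molecular foundation models) are ingested
through a generic reader.

Neither transform participates in end-to-end training: both are fitted (or
solved) once and then applied as pure functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import _nn
from .data_model import FeatureStore, ValidationError

__all__ = [
    "RWRConfig",
    "rwr_propagate",
    "rwr_solve_direct",
    "read_ppi_edge_list",
    "ppi_adjacency",
    "rwr_features",
    "fit_autoencoder",
    "load_embedding_table",
    "write_embedding_table",
    "DEFAULT_PPI_SCORE_MIN",
]

#: STRING-style confidence cutoff ("highest confidence") used to binarize
#: PPI edge scores before normalization
DEFAULT_PPI_SCORE_MIN = 900.0


@dataclass(frozen=True)
class RWRConfig:
    """Random-walk-with-restart parameters.

    restart_probability: probability of jumping back to the seed
    distribution at each step (mid-range default 0.5).
    """

    restart_probability: float = 0.5
    convergence_tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self):
        if not 0 < self.restart_probability <= 1:
            raise ValidationError("restart_probability must be in (0, 1]")
        if self.convergence_tolerance <= 0 or self.max_iterations <= 0:
            raise ValidationError("tolerance and iteration bound must be positive")


def _column_stochastic(adj: np.ndarray) -> np.ndarray:
    """Column-normalize an adjacency matrix; zero-degree nodes get a
    self-loop so the walk (and probability mass) stays put on them."""
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1]:
        raise ValidationError("adjacency must be square")
    if (adj < 0).any():
        raise ValidationError("adjacency weights must be non-negative")
    colsum = adj.sum(axis=0)
    w = adj.copy()
    for j in np.nonzero(colsum == 0)[0]:
        w[j, j] = 1.0
    colsum = w.sum(axis=0)
    return w / colsum


def rwr_propagate(adj: np.ndarray, seed_profile: np.ndarray,
                  config: RWRConfig = RWRConfig()) -> np.ndarray:
    """Iterate p <- c*p0 + (1-c)*W*p to convergence.

    ``adj`` is a symmetric non-negative adjacency matrix, ``seed_profile``
    a non-negative vector with at least one positive entry (normalized to
    sum 1 internally), ``W`` the column-stochastic transition matrix.  The
    returned stationary profile is non-negative and sums to 1.
    """
    p0 = np.asarray(seed_profile, dtype=float)
    if (p0 < 0).any():
        raise ValidationError("seed profile must be non-negative")
    total = p0.sum()
    if total <= 0:
        raise ValidationError("seed profile has no positive entry")
    p0 = p0 / total
    w = _column_stochastic(adj)
    c = config.restart_probability
    p = p0.copy()
    for _ in range(config.max_iterations):
        p_next = c * p0 + (1 - c) * (w @ p)
        if np.abs(p_next - p).sum() < config.convergence_tolerance:
            return p_next
        p = p_next
    return p


def rwr_solve_direct(adj: np.ndarray, seed_profile: np.ndarray,
                     config: RWRConfig = RWRConfig()) -> np.ndarray:
    """Closed-form stationary profile p = c (I - (1-c) W)^-1 p0."""
    p0 = np.asarray(seed_profile, dtype=float)
    p0 = p0 / p0.sum()
    w = _column_stochastic(adj)
    c = config.restart_probability
    n = w.shape[0]
    return c * np.linalg.solve(np.eye(n) - (1 - c) * w, p0)


def read_ppi_edge_list(path: str | Path) -> nx.Graph:
    """Weighted PPI edge list: protein_a, protein_b, score (CSV/TSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".edges", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    g = nx.Graph()
    for a, b, s in df.itertuples(index=False):
        g.add_edge(str(a), str(b), weight=float(s))
    return g


def ppi_adjacency(ppi: nx.Graph, score_min: float | None = DEFAULT_PPI_SCORE_MIN,
                  ) -> tuple[np.ndarray, list[str]]:
    """Adjacency matrix over sorted protein ids.

    With ``score_min`` set, edges are binarized at the confidence cutoff
    (edges below it are dropped); with None, raw weights are kept.
    """
    proteins = sorted(ppi.nodes)
    idx = {p: i for i, p in enumerate(proteins)}
    adj = np.zeros((len(proteins), len(proteins)))
    for a, b, data in ppi.edges(data=True):
        w = data.get("weight", 1.0)
        if score_min is not None:
            if w < score_min:
                continue
            w = 1.0
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = w
    return adj, proteins


def rwr_features(target_store: FeatureStore, ppi: nx.Graph,
                 target_universe: Sequence[str],
                 config: RWRConfig = RWRConfig(),
                 score_min: float | None = DEFAULT_PPI_SCORE_MIN,
                 name: str = "targets_rwr") -> FeatureStore:
    """Propagate each drug's binary target profile over the PPI network.

    The seed vector places uniform mass on the drug's targets that are in
    the network; drugs with no target in the network are omitted from the
    output store (they fall out downstream via feature-availability
    filtering).
    """
    adj, proteins = ppi_adjacency(ppi, score_min=score_min)
    pos = {p: i for i, p in enumerate(proteins)}
    universe = list(target_universe)
    payloads = {}
    for drug in target_store.entities():
        profile = np.asarray(target_store[drug])
        seed = np.zeros(len(proteins))
        for k, t in enumerate(universe):
            if profile[k] > 0 and t in pos:
                seed[pos[t]] = 1.0
        if seed.sum() == 0:
            continue
        payloads[drug] = rwr_propagate(adj, seed, config)
    if not payloads:
        raise ValidationError("no drug has a target inside the PPI network")
    return FeatureStore(name, "real_vector", payloads, dimension=len(proteins))


def fit_autoencoder(store: FeatureStore, latent_dim: int, seed: int,
                    hidden: Sequence[int] = (256,), epochs: int = 300,
                    learning_rate: float = 1e-3,
                    ) -> tuple[Callable[[np.ndarray], np.ndarray], list[float]]:
    """Fit a small reconstruction autoencoder on a store of binary vectors.

    Returns ``(encode, loss_trace)`` where ``encode`` maps any vector of
    the input dimension to its ``latent_dim``-dimensional code using the
    best-reconstruction-loss checkpoint, and ``loss_trace`` is the
    per-epoch mean squared reconstruction error.  Deterministic given the
    seed.
    """
    if store.dimension is None:
        raise ValidationError("autoencoder requires a vector store")
    if latent_dim >= store.dimension:
        raise ValidationError(
            f"latent_dim {latent_dim} must be < input dimension {store.dimension}")
    if len(store) < 2:
        raise ValidationError("autoencoder needs at least 2 payloads")
    x = np.stack([np.asarray(store[e], dtype=float) for e in sorted(store.entities())])
    rng = np.random.default_rng(seed)
    enc = _nn.MLP(store.dimension, list(hidden), latent_dim, rng)
    dec = _nn.MLP(latent_dim, list(reversed(hidden)), store.dimension, rng)
    params = enc.parameters() + dec.parameters()
    opt = _nn.Adam(params, lr=learning_rate)
    best_loss = np.inf
    best_state: list[np.ndarray] | None = None
    trace: list[float] = []
    xt = _nn.Tensor(x)
    for _ in range(epochs):
        opt.zero_grad()
        recon = dec(enc(xt))
        diff = recon - xt
        loss = (diff * diff).mean()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if trace[-1] < best_loss:
            best_loss = trace[-1]
            best_state = _nn.get_state(enc.parameters())

    enc_frozen = _nn.MLP(store.dimension, list(hidden), latent_dim,
                         np.random.default_rng(seed))
    _nn.set_state(enc_frozen.parameters(), best_state)

    def encode(vec: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(vec, dtype=float))
        if v.shape[1] != store.dimension:
            raise ValidationError(
                f"expected vectors of length {store.dimension}, got {v.shape[1]}")
        out = enc_frozen(_nn.Tensor(v)).data
        return out[0] if np.ndim(vec) == 1 else out

    return encode, trace


def encode_store(store: FeatureStore, encode: Callable[[np.ndarray], np.ndarray],
                 name: str | None = None) -> FeatureStore:
    """Apply a fitted encoder to every payload of a vector store."""
    payloads = {e: encode(np.asarray(store[e], dtype=float))
                for e in store.entities()}
    return FeatureStore(name or f"{store.feature_name}_encoded", "real_vector",
                        payloads)


def load_embedding_table(path: str | Path) -> FeatureStore:
    """Read a precomputed embedding table: id column + uniform numeric columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate id(s) {dupes[:3]}")
    values = df.iloc[:, 1:]
    try:
        mat = values.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric embedding values: {exc}")
    if mat.shape[1] == 0:
        raise ValidationError(f"{path}: no numeric columns")
    return FeatureStore(path.stem, "real_vector",
                        {i: mat[k] for k, i in enumerate(ids)},
                        dimension=mat.shape[1])


def write_embedding_table(store: FeatureStore, path: str | Path) -> None:
    if store.modality not in ("real_vector", "bit_vector"):
        raise ValidationError("only vector stores can be written as tables")
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    rows = {e: np.asarray(store[e], dtype=float) for e in store.entities()}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"dim_{i}" for i in range(store.dimension)])
    df.index.name = "id"
    df.to_csv(path, sep=sep)
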