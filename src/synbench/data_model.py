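"""Core domain types for drug-synergy triplet data.

A *triplet* is one observation (drug A, drug B, cell line) labeled with a
real-valued synergy score (e.g. S_mean or Loewe, consumed as given).  The
triplets of one cell line form a signed weighted network over drugs — the
object the network-randomization ablations operate on.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SynergyTriplet",
    "TripletTable",
    "CellLineSynergyNetwork",
    "FeatureStore",
    "ValidationError",
    "read_triplet_table",
    "write_triplet_table",
    "build_cell_line_networks",
    "read_edge_list",
    "write_edge_list",
]


class ValidationError(ValueError):
    """Raised when an input table or record violates a domain invariant."""


@dataclass(frozen=True, order=True)
class SynergyTriplet:
    """One drug–drug–cell-line observation with a synergy score.

    Stored in canonical order: ``drug_a`` lexicographically precedes
    ``drug_b``.  Use :meth:`make` to construct from unordered inputs.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    score: float
    n_replicates: int = 1

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValidationError(f"self-pair {self.drug_a!r} in {self.cell_line!r}")
        if self.drug_a > self.drug_b:
            raise ValidationError(
                f"triplet not in canonical order: {self.drug_a!r} > {self.drug_b!r}")
        if not math.isfinite(self.score):
            raise ValidationError(f"non-finite score for ({self.drug_a}, {self.drug_b})")
        if self.n_replicates < 0:
            raise ValidationError("n_replicates must be non-negative")

    @classmethod
    def make(cls, drug_a: str, drug_b: str, cell_line: str, score: float,
             n_replicates: int = 1) -> "SynergyTriplet":
        """Build a triplet, canonicalizing the drug order."""
        a, b = (drug_a, drug_b) if str(drug_a) <= str(drug_b) else (drug_b, drug_a)
        return cls(str(a), str(b), str(cell_line), float(score), int(n_replicates))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug_a, self.drug_b, self.cell_line)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


class TripletTable:
    """An ordered, keyed collection of :class:`SynergyTriplet`.

    Duplicate (pair, cell line) keys are rejected; the drug and cell-line
    universes are derived from the triplets unless given explicitly (a
    universe may be a superset of what is referenced).
    """

    def __init__(self, triplets: Iterable[SynergyTriplet],
                 drug_universe: set[str] | None = None,
                 cell_line_universe: set[str] | None = None):
        self.triplets: list[SynergyTriplet] = list(triplets)
        seen: set[tuple[str, str, str]] = set()
        for t in self.triplets:
            if t.key in seen:
                raise ValidationError(f"duplicate triplet key {t.key}")
            seen.add(t.key)
        referenced_drugs = {d for t in self.triplets for d in t.pair}
        referenced_cells = {t.cell_line for t in self.triplets}
        self.drug_universe = set(drug_universe) if drug_universe is not None else referenced_drugs
        self.cell_line_universe = (set(cell_line_universe)
                                   if cell_line_universe is not None else referenced_cells)
        if not referenced_drugs <= self.drug_universe:
            raise ValidationError("triplet references drug outside the drug universe")
        if not referenced_cells <= self.cell_line_universe:
            raise ValidationError("triplet references cell line outside the universe")

    def __len__(self) -> int:
        return len(self.triplets)

    def __iter__(self) -> Iterator[SynergyTriplet]:
        return iter(self.triplets)

    def __getitem__(self, i: int) -> SynergyTriplet:
        return self.triplets[i]

    def scores(self) -> np.ndarray:
        return np.array([t.score for t in self.triplets], dtype=float)

    def subset(self, indices: Sequence[int]) -> "TripletTable":
        return TripletTable([self.triplets[i] for i in indices],
                            drug_universe=self.drug_universe,
                            cell_line_universe=self.cell_line_universe)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_a": [t.drug_a for t in self.triplets],
                "drug_b": [t.drug_b for t in self.triplets],
                "cell_line": [t.cell_line for t in self.triplets],
                "score": [t.score for t in self.triplets],
                "n_replicates": [t.n_replicates for t in self.triplets],
            }
        )


@dataclass
class CellLineSynergyNetwork:
    """Per-cell-line signed weighted graph: drugs are nodes, each edge weight
    is the synergy score of that drug pair in this cell line.

    Edges are stored with endpoints in lexicographic order.  With
    ``multi_edge_allowed`` False (raw networks) at most one edge per pair;
    True (after strength-preserving rewiring) permits one positive and one
    negative edge on the same pair, never two of the same sign.
    """

    cell_line: str
    nodes: set[str] = field(default_factory=set)
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    multi_edge_allowed: bool = False

    def __post_init__(self):
        self.nodes = set(self.nodes)
        canon = []
        for u, v, w in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r} in {self.cell_line!r}")
            a, b = (u, v) if u <= v else (v, u)
            canon.append((a, b, float(w)))
        self.edges = canon
        self.nodes |= {n for u, v, _ in self.edges for n in (u, v)}
        self._check_multiplicity()

    def _check_multiplicity(self) -> None:
        if self.multi_edge_allowed:
            signed = Counter((u, v, w > 0) for u, v, w in self.edges)
            bad = [k for k, c in signed.items() if c > 1]
            if bad:
                raise ValidationError(f"duplicate same-sign edge(s): {bad[:3]}")
        else:
            pairs = Counter((u, v) for u, v, _ in self.edges)
            bad = [k for k, c in pairs.items() if c > 1]
            if bad:
                raise ValidationError(f"duplicate edge(s) on pair(s): {bad[:3]}")

    # ---- derived quantities --------------------------------------------
    def degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for u, v, _ in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def strength(self, sign: int = 0) -> dict[str, float]:
        """Node strength s(v)=sum of incident weights; sign=+1/-1 restricts to
        positive/negative edges, 0 sums all."""
        s = {n: 0.0 for n in self.nodes}
        for u, v, w in self.edges:
            if sign > 0 and w <= 0:
                continue
            if sign < 0 and w > 0:
                continue
            s[u] += w
            s[v] += w
        return s

    def pair_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.edges}

    def edge_multiset(self) -> Counter:
        return Counter((u, v, w) for u, v, w in self.edges)

    def sign_subgraph(self, sign: int) -> list[tuple[str, str, float]]:
        if sign > 0:
            return [e for e in self.edges if e[2] > 0]
        return [e for e in self.edges if e[2] <= 0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellLineSynergyNetwork):
            return NotImplemented
        return (self.cell_line == other.cell_line
                and self.nodes == other.nodes
                and self.edge_multiset() == other.edge_multiset())


VECTOR_MODALITIES = ("bit_vector", "real_vector")
MODALITIES = VECTOR_MODALITIES + ("text", "molecular_graph")


class FeatureStore:
    """Typed map from entity id to a feature payload.

    Vector modalities hold NumPy vectors of a fixed ``dimension``; ``text``
    holds strings (e.g. SMILES); ``molecular_graph`` holds
    :class:`~synbench.featurizers.AtomFeaturedGraph` objects.
    """

    def __init__(self, feature_name: str, modality: str,
                 payloads: Mapping[str, object], dimension: int | None = None):
        if modality not in MODALITIES:
            raise ValidationError(f"unknown modality {modality!r}")
        self.feature_name = feature_name
        self.modality = modality
        self.payloads: dict[str, object] = dict(payloads)
        if modality in VECTOR_MODALITIES:
            lengths = {len(np.asarray(v)) for v in self.payloads.values()}
            if dimension is None:
                if len(lengths) != 1:
                    raise ValidationError(
                        f"store {feature_name!r}: inconsistent or missing dimension")
                dimension = lengths.pop()
            elif lengths - {dimension}:
                raise ValidationError(
                    f"store {feature_name!r}: payload length != dimension {dimension}")
            self.payloads = {k: np.asarray(v, dtype=float)
                             for k, v in self.payloads.items()}
        self.dimension = dimension

    def __contains__(self, entity: str) -> bool:
        return entity in self.payloads

    def __getitem__(self, entity: str):
        return self.payloads[entity]

    def __len__(self) -> int:
        return len(self.payloads)

    def entities(self) -> list[str]:
        return list(self.payloads)

    def covers(self, entities: Iterable[str]) -> bool:
        return all(e in self.payloads for e in entities)


# ---- IO ------------------------------------------------------------------

_DEFAULT_COLUMNS = {"drug_a": "drug_a", "drug_b": "drug_b",
                    "cell_line": "cell_line", "score": "score"}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".edges", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_triplet_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None) -> TripletTable:
    """Read a delimited triplet table (CSV or TSV, header row required).

    ``column_map`` maps roles (drug_a, drug_b, cell_line, score, optionally
    n_replicates) to column names in the file.
    """
    cmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = _read_delimited(path)
    missing = [c for c in cmap.values() if c not in df.columns
               and c != cmap.get("n_replicates")]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    has_reps = cmap.get("n_replicates") in df.columns if "n_replicates" in cmap else \
        "n_replicates" in df.columns
    rep_col = cmap.get("n_replicates", "n_replicates")
    triplets = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        score = rec[cmap["score"]]
        try:
            score = float(score)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: row {i}: score {score!r} is not a number")
        if not math.isfinite(score):
            raise ValidationError(f"{path}: row {i}: non-finite score")
        triplets.append(SynergyTriplet.make(
            rec[cmap["drug_a"]], rec[cmap["drug_b"]], rec[cmap["cell_line"]],
            score, int(rec[rep_col]) if has_reps else 1))
    return TripletTable(triplets)


def write_triplet_table(table: TripletTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def build_cell_line_networks(table: TripletTable) -> dict[str, CellLineSynergyNetwork]:
    """One signed synergy network per cell line; each triplet becomes exactly
    one edge (weight = score) in its cell line's network."""
    if len(table) == 0:
        raise ValidationError("cannot build networks from an empty table")
    by_cell: dict[str, list[tuple[str, str, float]]] = {}
    for t in table:
        by_cell.setdefault(t.cell_line, []).append((t.drug_a, t.drug_b, t.score))
    return {c: CellLineSynergyNetwork(cell_line=c, edges=edges)
            for c, edges in sorted(by_cell.items())}


def write_edge_list(network: CellLineSynergyNetwork, path: str | Path) -> None:
    """Tab-delimited edge list with header; full-precision weights via repr."""
    with open(path, "w") as fh:
        fh.write("drug_a\tdrug_b\tweight\n")
        for u, v, w in network.edges:
            fh.write(f"{u}\t{v}\t{w!r}\n")


def read_edge_list(path: str | Path, cell_line: str | None = None,
                   multi_edge_allowed: bool = False) -> CellLineSynergyNetwork:
    path = Path(path)
    if cell_line is None:
        cell_line = path.name.split(".")[0]
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["drug_a", "drug_b", "weight"]:
            raise ValidationError(f"{path}: bad header {header!r}")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValidationError(f"{path}: line {i}: expected 3 fields")
            try:
                w = float(parts[2])
            except ValueError:
                raise ValidationError(f"{path}: line {i}: bad weight {parts[2]!r}")
            edges.append((parts[0], parts[1], w))
    return CellLineSynergyNetwork(cell_line=cell_line, edges=edges,
                                  multi_edge_allowed=multi_edge_allowed)
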