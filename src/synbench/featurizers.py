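"""Drug and cell-line input features.

Drug features: identifier one-hot, MACCS structural keys (166 bits),
hashed circular (Morgan) fingerprints at radius 2 in two widths (MFP, 256
bits; ECFP4, 1024 bits), binary target profiles, and atom-featured
molecular graphs parsed from SMILES.  Cell-line features: identifier
one-hot and gene-expression vectors, either the full profile or a
landmark-gene subset (missing landmark genes are dropped, not imputed).

All featurizers are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .data_model import FeatureStore, ValidationError

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; errors are raised instead

__all__ = [
    "FeaturizationError",
    "AtomFeaturedGraph",
    "one_hot_features",
    "fingerprint",
    "fingerprint_store",
    "smiles_to_graph",
    "graph_store",
    "smiles_store",
    "target_profile",
    "expression_features",
    "read_smiles_table",
    "FINGERPRINT_BITS",
    "default_atom_features",
    "ATOM_FEATURE_DIM",
]


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be featurized."""


#: fingerprint widths: MACCS structural keys and two hashed circular
#: fingerprints, both radius 2
FINGERPRINT_BITS = {"MACCS": 166, "MFP": 256, "ECFP4": 1024}
_MORGAN_RADIUS = 2


@dataclass(frozen=True)
class AtomFeaturedGraph:
    """Molecular graph: one node per heavy atom, one undirected edge per bond.

    ``atom_features`` is (n_atoms, feature_dim); ``bonds`` lists each bond
    once as an (i, j) pair of atom indices with i < j.
    """

    atom_features: np.ndarray
    bonds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        n = self.atom_features.shape[0]
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bad bond ({i}, {j}) for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a


def one_hot_features(entities: Sequence[str], name: str = "one_hot") -> FeatureStore:
    """Identity-style indicator features: the k-th entity gets a single 1 at
    index k of a |entities|-length bit vector."""
    entities = list(entities)
    if not entities:
        raise ValidationError("one_hot_features needs at least one entity")
    if len(set(entities)) != len(entities):
        raise ValidationError("duplicate identifiers in one-hot entity list")
    n = len(entities)
    eye = np.eye(n)
    return FeatureStore(name, "bit_vector",
                        {e: eye[k] for k, e in enumerate(entities)}, dimension=n)


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    return mol


def fingerprint(smiles: str, kind: str) -> np.ndarray:
    """Binary fingerprint of a molecule; lengths 166 / 256 / 1024 for
    MACCS / MFP / ECFP4."""
    if kind not in FINGERPRINT_BITS:
        raise ValidationError(f"unknown fingerprint kind {kind!r}")
    mol = _parse(smiles)
    if kind == "MACCS":
        # rdkit emits 167 bits with index 0 always unset; keep the 166 keys
        bits = np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.uint8)[1:]
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=_MORGAN_RADIUS, fpSize=FINGERPRINT_BITS[kind])
        bits = np.array(gen.GetFingerprint(mol), dtype=np.uint8)
    assert bits.shape == (FINGERPRINT_BITS[kind],)
    return bits


def fingerprint_store(smiles_map: Mapping[str, str], kind: str) -> FeatureStore:
    return FeatureStore(kind, "bit_vector",
                        {d: fingerprint(s, kind) for d, s in smiles_map.items()},
                        dimension=FINGERPRINT_BITS[kind])


# ---- atom featurization --------------------------------------------------

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se")
_MAX_DEGREE = 5
_MAX_HS = 4

#: element one-hot (+other) | degree one-hot | formal charge | aromatic |
#: implicit-H-count one-hot | in-ring flag
ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1) + (_MAX_DEGREE + 1) + 1 + 1 + (_MAX_HS + 1) + 1


def default_atom_features(atom: Chem.Atom) -> np.ndarray:
    """Standard atom descriptor: element, degree, formal charge, aromaticity,
    hydrogen count, ring membership."""
    v = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    v[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    off = len(_ELEMENTS) + 1
    v[off + min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    off += _MAX_DEGREE + 1
    v[off] = float(atom.GetFormalCharge())
    v[off + 1] = float(atom.GetIsAromatic())
    off += 2
    v[off + min(atom.GetTotalNumHs(), _MAX_HS)] = 1.0
    v[off + _MAX_HS + 1] = float(atom.IsInRing())
    return v


def smiles_to_graph(smiles: str, atom_featurizer=default_atom_features
                    ) -> AtomFeaturedGraph:
    """Heavy-atom molecular graph with per-atom feature vectors.

    Hydrogens stay implicit; the atom featurizer is pluggable (any function
    of an RDKit atom returning a fixed-length vector).
    """
    mol = _parse(smiles)
    feats = np.array([atom_featurizer(a) for a in mol.GetAtoms()])
    if feats.size == 0:
        raise FeaturizationError(f"molecule with no atoms: {smiles!r}")
    bonds = tuple(sorted(
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
        for b in mol.GetBonds()))
    return AtomFeaturedGraph(atom_features=feats, bonds=bonds)


def graph_store(smiles_map: Mapping[str, str], name: str = "mol_graph",
                atom_featurizer=default_atom_features) -> FeatureStore:
    return FeatureStore(name, "molecular_graph",
                        {d: smiles_to_graph(s, atom_featurizer)
                         for d, s in smiles_map.items()})


def smiles_store(smiles_map: Mapping[str, str], name: str = "smiles") -> FeatureStore:
    """Raw SMILES text store (validated to parse)."""
    for d, s in smiles_map.items():
        _parse(s)
    return FeatureStore(name, "text", dict(smiles_map))


def target_profile(drug_targets: Mapping[str, Iterable[str]],
                   target_universe: Sequence[str],
                   name: str = "targets") -> FeatureStore:
    """Binary target profiles: bit k of drug d is 1 iff the drug acts on
    target k of the ordered universe."""
    universe = list(target_universe)
    index = {t: k for k, t in enumerate(universe)}
    payloads = {}
    for d, targets in drug_targets.items():
        v = np.zeros(len(universe))
        for t in targets:
            if t not in index:
                raise ValidationError(f"target {t!r} of drug {d!r} outside universe")
            v[index[t]] = 1.0
        payloads[d] = v
    return FeatureStore(name, "bit_vector", payloads, dimension=len(universe))


def expression_features(matrix: pd.DataFrame,
                        gene_subset: Sequence[str] | str = "all",
                        name: str = "expression") -> FeatureStore:
    """Gene-expression vectors per cell line (rows = cell lines, columns =
    genes).  With a gene subset (e.g. landmark genes), only the genes present
    in the matrix are used, in the given order — absent genes are dropped
    rather than imputed."""
    if isinstance(gene_subset, str) and gene_subset == "all":
        genes = list(matrix.columns)
    else:
        genes = [g for g in gene_subset if g in matrix.columns]
        if not genes:
            raise ValidationError("gene subset has empty intersection with matrix")
    sub = matrix[genes]
    return FeatureStore(name, "real_vector",
                        {str(c): sub.loc[c].to_numpy(dtype=float) for c in sub.index},
                        dimension=len(genes))


def read_smiles_table(path: str | Path) -> dict[str, str]:
    """Two-column drug id -> SMILES table (CSV/TSV with header)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    ids, smiles = df.columns[0], df.columns[1]
    out = dict(zip(df[ids], df[smiles]))
    if len(out) != len(df):
        raise ValidationError(f"{path}: duplicate drug ids")
    return out
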