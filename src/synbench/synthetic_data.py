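"""Synthetic multi-cell-line synergy benchmark generator.

Emits everything the framework consumes — a triplet table, SMILES, binary
target tables, a gene-expression matrix, and a PPI edge list — with a
*controllable signal structure* that mirrors the hypotheses the ablation
studies probe:

- ``strength_driven``: score(i, j, c) = a_i^c + a_j^c + eps, with per-
  cell-line drug propensities a^c ~ Normal(0, 10^2).  The signal is
  additive in drug identity and carries no information in any feature —
  the regime where a model can only exploit the per-drug synergy-score
  distribution (the topological shortcut).
- ``feature_driven``: score(i, j, c) = additive + bilinear-interaction
  function of latent drug vectors x_i and a latent cell-line vector z_c,
  which are (noisily) embedded into the emitted drug-feature and
  expression tables.  Here features genuinely carry the signal, and the
  pairwise bilinear term cannot be recovered by memorizing drugs.
- ``noise_only``: pure noise; any model's test correlation is ~0.

Drugs are assigned real small-molecule SMILES from a shipped library
(chemically unrelated to the planted signal by construction).  A fraction
of triplets can be emitted as raw replicate records with jitter, plus
planted high-variance replicate groups, to exercise the cleaning pipeline.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (FeatureStore, SynergyTriplet, TripletTable,
                         ValidationError, write_triplet_table)
from .dataset_prep import RawSynergyRecord

__all__ = ["SynthConfig", "SyntheticDataset", "generate_dataset",
           "plant_replicate_conflict", "write_dataset", "load_smiles_library"]

#: per-cell-line drug propensity scale (strength_driven), chosen to give
#: score spreads loosely comparable to S_mean-style synergy scores
PROPENSITY_SD = 10.0
LATENT_DIM = 8
N_GENES = 50
N_PROTEINS = 60
EMBED_DIM = 16
FEATURE_NOISE_SD = 0.1


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; the defaults are the benchmark's study conditions."""

    n_drugs: int = 30
    n_cell_lines: int = 5
    pair_density: float = 0.5
    signal: str = "strength_driven"
    noise_sd: float = 5.0
    replicate_rate: float = 0.0
    replicate_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 3:
            raise ValidationError("need at least 3 drugs for pair sampling")
        if not 0 < self.pair_density <= 1:
            raise ValidationError("pair_density must be in (0, 1]")
        if self.signal not in ("strength_driven", "feature_driven", "noise_only"):
            raise ValidationError(f"unknown signal mode {self.signal!r}")
        if self.noise_sd < 0 or self.replicate_jitter_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        if not 0 <= self.replicate_rate <= 1:
            raise ValidationError("replicate_rate must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """Everything a hermetic experiment needs, plus the planted truth."""

    config: SynthConfig
    table: TripletTable
    smiles: dict[str, str]
    drug_targets: dict[str, list[str]]
    target_universe: list[str]
    expression: pd.DataFrame  # cell line x gene
    ppi_edges: pd.DataFrame  # protein_a, protein_b, score
    drug_features: FeatureStore  # latent-embedding drug vectors
    raw_records: list[RawSynergyRecord] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def stores(self) -> dict[str, FeatureStore]:
        """Feature stores keyed the way model specs reference them."""
        from .featurizers import one_hot_features
        drugs = sorted(self.table.drug_universe)
        cells = sorted(self.table.cell_line_universe)
        return {
            "drug_one_hot": one_hot_features(drugs, name="drug_one_hot"),
            "cell_one_hot": one_hot_features(cells, name="cell_one_hot"),
            "drug_latent": self.drug_features,
            "expression": FeatureStore(
                "expression", "real_vector",
                {c: self.expression.loc[c].to_numpy(dtype=float)
                 for c in cells if c in self.expression.index}),
        }


def load_smiles_library() -> list[str]:
    text = (importlib.resources.files("synbench") / "data" /
            "smiles_library.txt").read_text()
    return [s for s in text.splitlines() if s.strip()]


def _sample_pairs(n_drugs: int, density: float,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    all_pairs = [(i, j) for i in range(n_drugs) for j in range(i + 1, n_drugs)]
    k = max(1, int(round(density * len(all_pairs))))
    chosen = rng.choice(len(all_pairs), size=k, replace=False)
    return [all_pairs[i] for i in sorted(chosen)]


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Deterministically generate a full synthetic benchmark from a config."""
    rng = np.random.default_rng(config.seed)
    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    cells = [f"C{k:02d}" for k in range(config.n_cell_lines)]

    library = load_smiles_library()
    picks = rng.permutation(len(library))
    smiles = {d: library[picks[i % len(library)]] for i, d in enumerate(drugs)}

    # latent structure (always drawn, whether or not the signal uses it,
    # so feature tables look alike across signal modes)
    x = rng.normal(0.0, 1.0, size=(config.n_drugs, LATENT_DIM))
    z = rng.normal(0.0, 1.0, size=(config.n_cell_lines, LATENT_DIM))
    u = rng.normal(0.0, 1.0, size=LATENT_DIM) / np.sqrt(LATENT_DIM)
    v = rng.normal(0.0, 1.0, size=LATENT_DIM) / np.sqrt(LATENT_DIM)
    m_bilinear = rng.normal(0.0, 1.0, size=(LATENT_DIM, LATENT_DIM))
    m_bilinear = (m_bilinear + m_bilinear.T) / np.sqrt(2 * LATENT_DIM)
    propensity = rng.normal(0.0, PROPENSITY_SD,
                            size=(config.n_cell_lines, config.n_drugs))

    pairs = _sample_pairs(config.n_drugs, config.pair_density, rng)
    triplets = []
    for k, cell in enumerate(cells):
        for i, j in pairs:
            eps = rng.normal(0.0, config.noise_sd)
            if config.signal == "strength_driven":
                score = propensity[k, i] + propensity[k, j] + eps
            elif config.signal == "feature_driven":
                additive = 4.0 * (u @ x[i] + u @ x[j])
                interaction = 8.0 * (x[i] @ m_bilinear @ x[j])
                cell_term = 4.0 * (v @ z[k])
                score = additive + interaction + cell_term + eps
            else:  # noise_only
                score = eps
            triplets.append(SynergyTriplet.make(drugs[i], drugs[j], cell, score))
    table = TripletTable(triplets, drug_universe=set(drugs),
                         cell_line_universe=set(cells))

    # emitted drug features: fixed noisy linear embedding of the latents
    proj = rng.normal(0.0, 1.0, size=(LATENT_DIM, EMBED_DIM)) / np.sqrt(LATENT_DIM)
    feats = x @ proj + rng.normal(0.0, FEATURE_NOISE_SD,
                                  size=(config.n_drugs, EMBED_DIM))
    drug_features = FeatureStore(
        "drug_latent", "real_vector",
        {d: feats[i] for i, d in enumerate(drugs)}, dimension=EMBED_DIM)

    # expression matrix embedding the cell latents
    gene_proj = rng.normal(0.0, 1.0, size=(LATENT_DIM, N_GENES)) / np.sqrt(LATENT_DIM)
    expr = z @ gene_proj + rng.normal(0.0, FEATURE_NOISE_SD,
                                      size=(config.n_cell_lines, N_GENES))
    expression = pd.DataFrame(expr, index=cells,
                              columns=[f"G{g:03d}" for g in range(N_GENES)])

    # target table + PPI over a shared protein universe
    proteins = [f"P{p:03d}" for p in range(N_PROTEINS)]
    drug_targets = {
        d: sorted(rng.choice(proteins, size=rng.integers(1, 5), replace=False))
        for d in drugs}
    target_universe = sorted({t for ts in drug_targets.values() for t in ts})
    edges = set()
    while len(edges) < 3 * N_PROTEINS:
        a, b = rng.integers(0, N_PROTEINS, size=2)
        if a != b:
            edges.add((min(a, b), max(a, b)))
    ppi = pd.DataFrame(
        [(proteins[a], proteins[b], int(rng.integers(150, 1000)))
         for a, b in sorted(edges)],
        columns=["protein_a", "protein_b", "score"])

    raw_records = _emit_replicates(table, config, rng)
    truth = {"propensity": propensity, "drug_latents": x, "cell_latents": z,
             "drugs": drugs, "cells": cells}
    return SyntheticDataset(config=config, table=table, smiles=smiles,
                            drug_targets=drug_targets,
                            target_universe=target_universe,
                            expression=expression, ppi_edges=ppi,
                            drug_features=drug_features,
                            raw_records=raw_records, truth=truth)


def _emit_replicates(table: TripletTable, config: SynthConfig,
                     rng: np.random.Generator) -> list[RawSynergyRecord]:
    """Raw records: most triplets once, a seeded fraction as 2-3 concordant
    replicates with jitter."""
    records = []
    for t in table:
        if rng.random() < config.replicate_rate:
            n_rep = int(rng.integers(2, 4))
            for _ in range(n_rep):
                records.append(RawSynergyRecord(
                    t.drug_a, t.drug_b, t.cell_line,
                    t.score + rng.normal(0.0, config.replicate_jitter_sd)))
        else:
            records.append(RawSynergyRecord(t.drug_a, t.drug_b, t.cell_line,
                                            t.score))
    return records


def plant_replicate_conflict(table: TripletTable, n_conflicts: int,
                             sd_above: float = 0.2, seed: int = 0,
                             concordant_jitter_sd: float = 0.02
                             ) -> list[RawSynergyRecord]:
    """Emit raw replicate records in which exactly ``n_conflicts`` chosen
    triplets get a replicate pair with sample SD > the consensus filter's
    threshold; every other triplet gets a concordant pair.

    For a replicate pair the sample SD is |delta| / sqrt(2), so the
    conflicting pairs are separated by sd_above * sqrt(2) and the
    concordant ones are jittered well below the threshold.
    """
    if n_conflicts > len(table):
        raise ValidationError("more conflicts requested than triplets")
    if sd_above <= 0.1:
        raise ValidationError("sd_above must exceed the 0.1 filter threshold")
    rng = np.random.default_rng(seed)
    conflict_idx = set(rng.choice(len(table), size=n_conflicts, replace=False)
                       .tolist())
    records = []
    for i, t in enumerate(table):
        if i in conflict_idx:
            half = sd_above * np.sqrt(2.0) / 2.0
            records.append(RawSynergyRecord(t.drug_a, t.drug_b, t.cell_line,
                                            t.score - half))
            records.append(RawSynergyRecord(t.drug_a, t.drug_b, t.cell_line,
                                            t.score + half))
        else:
            jit = min(concordant_jitter_sd, 0.09 / np.sqrt(2.0))
            records.append(RawSynergyRecord(t.drug_a, t.drug_b, t.cell_line,
                                            t.score - jit / 2))
            records.append(RawSynergyRecord(t.drug_a, t.drug_b, t.cell_line,
                                            t.score + jit / 2))
    return records


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit the file formats the rest of the framework reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_triplet_table(dataset.table, outdir / "triplets.csv")
    pd.DataFrame(sorted(dataset.smiles.items()),
                 columns=["drug", "smiles"]).to_csv(outdir / "smiles.csv",
                                                    index=False)
    rows = [(d, t) for d, ts in sorted(dataset.drug_targets.items()) for t in ts]
    pd.DataFrame(rows, columns=["drug", "target"]).to_csv(
        outdir / "drug_targets.csv", index=False)
    dataset.expression.rename_axis("cell_line").to_csv(outdir / "expression.csv")
    dataset.ppi_edges.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    if dataset.raw_records:
        pd.DataFrame([(r.drug_a_name, r.drug_b_name, r.cell_line, r.score)
                      for r in dataset.raw_records],
                     columns=["drug_a_name", "drug_b_name", "cell_line",
                              "score"]).to_csv(outdir / "raw_records.csv",
                                               index=False)
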