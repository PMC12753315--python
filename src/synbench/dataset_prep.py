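"""Cleaning pipeline for raw combination-screen records.

Mirrors the standard preparation of a DrugComb-style export before model
training: drop mono-therapy rows, canonicalize drug names to compound
identifiers (excluding unmapped or ambiguous names), collapse replicate
measurements to a consensus score behind a standard-deviation filter,
restrict to triplets with full feature coverage, and drop cell lines that
carry too small a share of the data.

Each stage only removes or merges rows — no data is invented — so the
output triplet key set of every stage is a subset of its input's.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import (FeatureStore, SynergyTriplet, TripletTable,
                         ValidationError)

logger = logging.getLogger(__name__)

__all__ = [
    "RawSynergyRecord",
    "IdentifierMap",
    "ExclusionReport",
    "read_raw_records",
    "remove_mono_therapy",
    "canonicalize_drugs",
    "consensus_scores",
    "filter_feature_availability",
    "filter_cell_line_coverage",
    "prepare_dataset",
]

#: replicate groups whose sample SD exceeds this are discarded
DEFAULT_SD_THRESHOLD = 0.1
#: minimum share of triplets a cell line must carry to be retained
DEFAULT_MIN_CELL_FRACTION = 0.05


@dataclass(frozen=True)
class RawSynergyRecord:
    """One raw screen row; ``drug_b_name`` empty means mono-therapy."""

    drug_a_name: str
    drug_b_name: str  # "" for mono-therapy rows
    cell_line: str
    score: float
    study_tag: str = ""

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValidationError(
                f"non-finite score for ({self.drug_a_name}, {self.drug_b_name})")

    @property
    def is_mono(self) -> bool:
        return self.drug_b_name == "" or pd.isna(self.drug_b_name)


class IdentifierMap:
    """Map from drug name to candidate compound identifiers.

    Each candidate carries a canonical structure string (e.g. canonical
    SMILES).  A name is *ambiguous* when it maps to two or more identifiers
    with differing structure strings — typically different salt forms —
    and is excluded downstream.
    """

    def __init__(self, entries: Mapping[str, Sequence[tuple[str, str]]]):
        # entries: name -> [(compound_id, structure_string), ...]
        self.entries = {k: list(v) for k, v in entries.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "IdentifierMap":
        """Read a 3-column table: name, compound_id, structure."""
        path = Path(path)
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
        entries: dict[str, list[tuple[str, str]]] = {}
        for name, cid, structure in df.itertuples(index=False):
            entries.setdefault(name, []).append((cid, structure))
        return cls(entries)

    def resolve(self, name: str) -> str | None:
        """Return the canonical identifier, or None if unmapped/ambiguous."""
        cands = self.entries.get(name)
        if not cands:
            return None
        structures = {s for _, s in cands}
        if len(structures) > 1:
            return None
        return cands[0][0]

    def status(self, name: str) -> str:
        cands = self.entries.get(name)
        if not cands:
            return "unmapped"
        if len({s for _, s in cands}) > 1:
            return "ambiguous"
        return "mapped"


@dataclass
class ExclusionReport:
    """Counts of records dropped by canonicalization, by reason."""

    unmapped: int = 0
    ambiguous: int = 0
    retained: int = 0

    @property
    def total(self) -> int:
        return self.unmapped + self.ambiguous + self.retained

    def to_dict(self) -> dict[str, int]:
        return {"unmapped": self.unmapped, "ambiguous": self.ambiguous,
                "retained": self.retained}


def read_raw_records(path: str | Path,
                     column_map: Mapping[str, str] | None = None
                     ) -> list[RawSynergyRecord]:
    cmap = {"drug_a_name": "drug_a_name", "drug_b_name": "drug_b_name",
            "cell_line": "cell_line", "score": "score", "study_tag": "study_tag"}
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    out = []
    for rec in df.to_dict("records"):
        b = rec.get(cmap["drug_b_name"], "")
        out.append(RawSynergyRecord(
            drug_a_name=str(rec[cmap["drug_a_name"]]),
            drug_b_name="" if pd.isna(b) else str(b),
            cell_line=str(rec[cmap["cell_line"]]),
            score=float(rec[cmap["score"]]),
            study_tag=str(rec.get(cmap["study_tag"], "") or "")))
    return out


def remove_mono_therapy(records: Iterable[RawSynergyRecord]) -> list[RawSynergyRecord]:
    """Keep only true combination rows (both drug names present)."""
    return [r for r in records if not r.is_mono]


def canonicalize_drugs(records: Iterable[RawSynergyRecord], id_map: IdentifierMap
                       ) -> tuple[list[RawSynergyRecord], ExclusionReport]:
    """Replace drug names by canonical compound identifiers.

    Records touching an unmapped name, or a name that maps to multiple
    identifiers with differing structures, are dropped and tallied.
    """
    report = ExclusionReport()
    out = []
    for r in records:
        statuses = {id_map.status(r.drug_a_name), id_map.status(r.drug_b_name)}
        if "unmapped" in statuses:
            report.unmapped += 1
            continue
        if "ambiguous" in statuses:
            report.ambiguous += 1
            continue
        out.append(RawSynergyRecord(
            drug_a_name=id_map.resolve(r.drug_a_name),
            drug_b_name=id_map.resolve(r.drug_b_name),
            cell_line=r.cell_line, score=r.score, study_tag=r.study_tag))
        report.retained += 1
    return out, report


def consensus_scores(records: Iterable[RawSynergyRecord],
                     sd_threshold: float = DEFAULT_SD_THRESHOLD) -> TripletTable:
    """Collapse replicates to one consensus triplet per (pair, cell line).

    Groups with >= 2 replicates whose sample standard deviation (n-1
    denominator) exceeds ``sd_threshold`` are excluded as inconsistent;
    surviving groups are averaged.  Singleton groups always pass (the SD is
    undefined for n=1; the filter targets replicate disagreement).
    """
    groups: dict[tuple[str, str, str], list[float]] = {}
    for r in records:
        a, b = sorted((r.drug_a_name, r.drug_b_name))
        groups.setdefault((a, b, r.cell_line), []).append(r.score)
    triplets = []
    n_dropped = 0
    for (a, b, c), scores in sorted(groups.items()):
        if len(scores) >= 2 and statistics.stdev(scores) > sd_threshold:
            n_dropped += 1
            continue
        triplets.append(SynergyTriplet.make(
            a, b, c, sum(scores) / len(scores), n_replicates=len(scores)))
    if n_dropped:
        logger.info("consensus_scores: dropped %d replicate group(s) with SD > %g",
                    n_dropped, sd_threshold)
    return TripletTable(triplets)


def filter_feature_availability(table: TripletTable,
                                stores: Sequence[FeatureStore],
                                cell_feature: FeatureStore | None = None
                                ) -> TripletTable:
    """Keep triplets whose both drugs are covered by every drug store and
    whose cell line is covered by the cell store (if given)."""
    kept = []
    for t in table:
        if all(t.drug_a in s and t.drug_b in s for s in stores) and \
                (cell_feature is None or t.cell_line in cell_feature):
            kept.append(t)
    return TripletTable(kept, drug_universe=table.drug_universe,
                        cell_line_universe=table.cell_line_universe)


def filter_cell_line_coverage(table: TripletTable,
                              min_fraction: float = DEFAULT_MIN_CELL_FRACTION,
                              iterate: bool = False) -> TripletTable:
    """Drop cell lines carrying fewer than ``min_fraction`` of the triplets.

    Counts are taken against the input table in a single pass (a cell line
    with exactly the threshold share is retained).  With ``iterate`` True
    the filter is reapplied on its own output until a fixed point.
    """
    if not 0 < min_fraction < 1:
        raise ValidationError("min_fraction must be in (0, 1)")
    current = table
    while True:
        total = len(current)
        if total == 0:
            logger.warning("coverage filter applied to an empty table")
            return current
        counts: dict[str, int] = {}
        for t in current:
            counts[t.cell_line] = counts.get(t.cell_line, 0) + 1
        keep = {c for c, n in counts.items() if n >= min_fraction * total}
        filtered = TripletTable([t for t in current if t.cell_line in keep],
                                drug_universe=current.drug_universe,
                                cell_line_universe=keep)
        if len(filtered) == 0:
            logger.warning("coverage filter removed every triplet")
        if not iterate or len(filtered) == len(current):
            return filtered
        current = filtered


def prepare_dataset(records: Iterable[RawSynergyRecord],
                    id_map: IdentifierMap | None = None,
                    drug_stores: Sequence[FeatureStore] = (),
                    cell_feature: FeatureStore | None = None,
                    sd_threshold: float = DEFAULT_SD_THRESHOLD,
                    min_cell_fraction: float = DEFAULT_MIN_CELL_FRACTION,
                    coverage_after_subsetting: bool = True,
                    ) -> tuple[TripletTable, ExclusionReport]:
    """Run the full cleaning pipeline in the standard order.

    The coverage filter runs per feature subset (after feature-availability
    subsetting) by default, since under-represented cell lines are defined
    relative to the data a model will actually see; set
    ``coverage_after_subsetting`` False to apply it beforehand.
    """
    recs = remove_mono_therapy(records)
    report = ExclusionReport(retained=len(recs))
    if id_map is not None:
        recs, report = canonicalize_drugs(recs, id_map)
    table = consensus_scores(recs, sd_threshold=sd_threshold)
    if not coverage_after_subsetting:
        table = filter_cell_line_coverage(table, min_fraction=min_cell_fraction)
    if drug_stores or cell_feature is not None:
        table = filter_feature_availability(table, drug_stores, cell_feature)
    if coverage_after_subsetting:
        table = filter_cell_line_coverage(table, min_fraction=min_cell_fraction)
    return table, report
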