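"""Leakage-controlled train/validation/test splits.

Four strategies, each holding a machine-checkable contract against data
leakage between training and evaluation:

- ``leave_triplet``: triplets assigned at random; only exact
  (drug, drug, cell line) keys are guaranteed unseen.
- ``leave_drug_pair``: unordered drug pairs are the sampling unit, so no
  pair in validation/test ever appears in training (in any cell line).
- ``leave_drug``: drugs are partitioned; training uses only train-drugs,
  and every test triplet touches at least one held-out drug (strict mode
  requires both).
- ``leave_cell_line``: cell lines are partitioned; each partition's
  triplets use only its own cell lines.

``verify_leakage`` re-derives the contract from the raw triplets, so a
split can always be audited independently of how it was produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import TripletTable, ValidationError

__all__ = ["STRATEGIES", "DataSplit", "make_split", "verify_leakage",
           "save_split", "load_split", "DEFAULT_FRACTIONS"]

STRATEGIES = ("leave_triplet", "leave_drug_pair", "leave_drug", "leave_cell_line")
DEFAULT_FRACTIONS = (0.7, 0.1, 0.2)


@dataclass
class DataSplit:
    strategy: str
    train: list[int]
    validation: list[int]
    test: list[int]
    seed: int
    fractions: tuple[float, float, float]
    strict_leave_drug: bool = False

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValidationError("split partitions overlap")

    def partitions(self) -> dict[str, list[int]]:
        return {"train": self.train, "validation": self.validation,
                "test": self.test}


def _check_fractions(fractions: Sequence[float]) -> tuple[float, float, float]:
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or \
            abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must be 3 positives summing to 1, "
                              f"got {tuple(fractions)}")
    return tuple(float(f) for f in fractions)


def _greedy_group_split(groups: list[tuple[object, list[int]]], n_total: int,
                        fractions: tuple[float, float, float],
                        rng: np.random.Generator
                        ) -> tuple[list[int], list[int], list[int]]:
    """Shuffle groups, then fill test, validation, train to their triplet
    quotas in that order (smallest partitions first keeps realized
    fractions close to the request)."""
    order = rng.permutation(len(groups))
    assigned: list[list[list[int]]] = [[], [], []]  # train, val, test (groups)
    targets = [f * n_total for f in fractions]

    def size(p: int) -> int:
        return sum(len(g) for g in assigned[p])

    # priority on ties: fill test, then validation, then train
    for gi in order:
        _, members = groups[gi]
        deficits = [targets[p] - size(p) for p in range(3)]
        best = max((2, 1, 0), key=lambda p: (deficits[p], p))
        assigned[best].append(list(members))
    # repair: train and test must each hold at least one group (validation
    # may stay empty on very small tables); donate the smallest group from
    # the best-stocked partition
    for needy in (2, 0):
        if not assigned[needy]:
            spareable = [p for p in range(3) if p != needy and assigned[p]
                         and (len(assigned[p]) > 1 or p == 1)]
            if spareable:
                donor = max(spareable, key=lambda p: len(assigned[p]))
                smallest = min(range(len(assigned[donor])),
                               key=lambda k: len(assigned[donor][k]))
                assigned[needy].append(assigned[donor].pop(smallest))
    return tuple(sorted(i for g in assigned[p] for i in g) for p in range(3))


def make_split(table: TripletTable, strategy: str,
               fractions: Sequence[float] = DEFAULT_FRACTIONS,
               seed: int = 0, strict_leave_drug: bool = False) -> DataSplit:
    """Deterministic leakage-controlled split of a triplet table.

    Grouped sampling cannot hit the requested fractions exactly; groups are
    shuffled by the seed and assigned greedily until each partition's
    triplet quota is met, so the realized fraction deviates by at most the
    largest group's share of the table.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    fractions = _check_fractions(fractions)
    n = len(table)
    if n < 3:
        raise ValidationError("table too small to split into three partitions")
    rng = np.random.default_rng(seed)

    if strategy == "leave_triplet":
        groups = [(i, [i]) for i in range(n)]
    elif strategy == "leave_drug_pair":
        by_pair: dict[tuple[str, str], list[int]] = {}
        for i, t in enumerate(table):
            by_pair.setdefault(t.pair, []).append(i)
        groups = sorted(by_pair.items())
    elif strategy == "leave_cell_line":
        by_cell: dict[str, list[int]] = {}
        for i, t in enumerate(table):
            by_cell.setdefault(t.cell_line, []).append(i)
        if len(by_cell) < 2:
            raise ValidationError("leave_cell_line needs at least 2 cell lines")
        groups = sorted(by_cell.items())
    else:  # leave_drug
        return _make_leave_drug_split(table, fractions, seed, strict_leave_drug, rng)

    train, val, test = _greedy_group_split(groups, n, fractions, rng)
    # validation may legitimately be empty on very small tables (e.g. a
    # 2-cell-line leave_cell_line split); train and test never may
    for name, part in (("train", train), ("test", test)):
        if not part:
            raise ValidationError(
                f"{strategy}: partition {name!r} is empty; too few groups "
                f"for the requested fractions")
    return DataSplit(strategy, train, val, test, seed, fractions)


def _make_leave_drug_split(table: TripletTable,
                           fractions: tuple[float, float, float], seed: int,
                           strict: bool, rng: np.random.Generator) -> DataSplit:
    drugs = sorted({d for t in table for d in t.pair})
    if len(drugs) < 3:
        raise ValidationError("leave_drug needs at least 3 drugs")
    order = [drugs[i] for i in rng.permutation(len(drugs))]
    n = len(table)
    test_d: set[str] = set()
    val_d: set[str] = set()

    def count_touching(held: set[str], excluded: set[str]) -> int:
        cnt = 0
        for t in table:
            ds = set(t.pair)
            if ds & excluded:
                continue
            if (ds <= held) if strict else (ds & held):
                cnt += 1
        return cnt

    while order and count_touching(test_d, set()) < fractions[2] * n:
        test_d.add(order.pop())
    while order and count_touching(val_d, test_d) < fractions[1] * n:
        val_d.add(order.pop())

    train, val, test = [], [], []
    for i, t in enumerate(table):
        ds = set(t.pair)
        in_test = (ds <= test_d) if strict else bool(ds & test_d)
        if in_test:
            test.append(i)
            continue
        if ds & test_d:
            continue  # strict mode: mixed seen/held-out triplets are dropped
        in_val = (ds <= val_d) if strict else bool(ds & val_d)
        if in_val:
            val.append(i)
        elif not ds & val_d:
            train.append(i)
    if not (train and test):
        raise ValidationError("leave_drug: train or test came out empty; "
                              "table too small for the requested fractions")
    return DataSplit("leave_drug", train, val, test, seed, fractions,
                     strict_leave_drug=strict)


def verify_leakage(split: DataSplit, table: TripletTable) -> list[str]:
    """Audit a split against its strategy's leakage contract.

    Returns a list of human-readable violation descriptions; empty iff the
    contract holds.  Both validation and test are checked against train.
    """
    violations: list[str] = []
    train = [table[i] for i in split.train]
    held = {"validation": [table[i] for i in split.validation],
            "test": [table[i] for i in split.test]}

    if split.strategy == "leave_triplet":
        train_keys = {t.key for t in train}
        for part, ts in held.items():
            for t in ts:
                if t.key in train_keys:
                    violations.append(f"{part}: triplet {t.key} also in train")
    elif split.strategy == "leave_drug_pair":
        train_pairs = {t.pair for t in train}
        for part, ts in held.items():
            for pair in sorted({t.pair for t in ts} & train_pairs):
                violations.append(f"{part}: drug pair {pair} also in train")
    elif split.strategy == "leave_drug":
        train_drugs = {d for t in train for d in t.pair}
        for part, ts in held.items():
            for t in ts:
                ds = set(t.pair)
                if split.strict_leave_drug:
                    if ds & train_drugs:
                        violations.append(
                            f"{part}: triplet {t.key} touches train drug(s) "
                            f"{sorted(ds & train_drugs)}")
                elif ds <= train_drugs:
                    violations.append(
                        f"{part}: triplet {t.key} has no held-out drug")
    else:  # leave_cell_line
        cells = {part: {t.cell_line for t in ts} for part, ts in held.items()}
        cells["train"] = {t.cell_line for t in train}
        for part in ("validation", "test"):
            for c in sorted(cells[part] & cells["train"]):
                violations.append(f"{part}: cell line {c!r} also in train")
        for c in sorted(cells["validation"] & cells["test"]):
            violations.append(f"test: cell line {c!r} also in validation")
    return violations


def save_split(split: DataSplit, table: TripletTable, outdir: str | Path) -> None:
    """Write train.idx / val.idx / test.idx plus a JSON manifest with the
    verifier's report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, idx in (("train", split.train), ("val", split.validation),
                      ("test", split.test)):
        (outdir / f"{name}.idx").write_text("\n".join(map(str, idx)) + "\n")
    manifest = {
        "strategy": split.strategy,
        "seed": split.seed,
        "fractions": list(split.fractions),
        "strict_leave_drug": split.strict_leave_drug,
        "sizes": {"train": len(split.train), "validation": len(split.validation),
                  "test": len(split.test)},
        "leakage_violations": verify_leakage(split, table),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_split(outdir: str | Path) -> DataSplit:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    idx = {name: [int(x) for x in (outdir / f"{name}.idx").read_text().split()]
           for name in ("train", "val", "test")}
    return DataSplit(manifest["strategy"], idx["train"], idx["val"], idx["test"],
                     manifest["seed"], tuple(manifest["fractions"]),
                     strict_leave_drug=manifest.get("strict_leave_drug", False))
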