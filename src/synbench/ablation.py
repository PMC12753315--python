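"""Ablation instruments: feature shuffling and signed-network randomization.

Three network randomizations probe whether a model's performance comes
from drug-pair semantics or from aggregate (topological) shortcuts:

- degree-preserving rewiring: Maslov–Sneppen double-edge swaps, applied to
  the positive and negative edge sets separately, with the weights of each
  sign redistributed at random over the new edges;
- strength-preserving rewiring: simulated annealing over double-edge swaps
  and weight swaps, minimizing the squared error between the original and
  current per-node per-sign strength sequences;
- weight permutation: edges kept, weights permuted within each sign.

After strength-preserving rewiring the same drug pair may carry one
positive and one negative edge; such networks are flagged
``multi_edge_allowed``.  Training variants rebuild a training table from
rewired per-cell-line networks while validation and test always remain the
originals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import (CellLineSynergyNetwork, FeatureStore, SynergyTriplet,
                         TripletTable, ValidationError,
                         build_cell_line_networks)
from .splits import DataSplit

__all__ = [
    "RewireResult",
    "AnnealSchedule",
    "shuffle_features",
    "rewire_degree_preserving",
    "rewire_strength_preserving",
    "permute_edge_weights",
    "build_training_variant",
    "rewire_training_table",
]

#: attempted double-edge swaps per edge (mixing heuristic)
DEFAULT_SWAP_FACTOR = 10.0


@dataclass
class RewireResult:
    method: str
    network: CellLineSynergyNetwork
    seed: int
    retained_fraction: float
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.retained_fraction <= 1.0:
            raise ValidationError("retained_fraction must be in [0, 1]")


def shuffle_features(store: FeatureStore, seed: int,
                     derangement: bool = False) -> FeatureStore:
    """Reassign payloads across entities by a uniform random permutation.

    The multiset of payloads and the entity id set are unchanged; only the
    entity-to-payload assignment moves.  With ``derangement`` True the
    permutation is resampled until it has no fixed point (when possible).
    """
    entities = sorted(store.entities())
    if len(entities) < 2:
        return FeatureStore(store.feature_name, store.modality,
                            dict(store.payloads), dimension=store.dimension)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(entities))
    if derangement:
        while (perm == np.arange(len(entities))).any():
            perm = rng.permutation(len(entities))
    payloads = {entities[i]: store.payloads[entities[perm[i]]]
                for i in range(len(entities))}
    return FeatureStore(store.feature_name, store.modality, payloads,
                        dimension=store.dimension)


def _retained_fraction(original: CellLineSynergyNetwork,
                       edges: Sequence[tuple[str, str, float]]) -> float:
    orig_pairs = original.pair_set()
    if not orig_pairs:
        return 1.0
    new_pairs = {(u, v) for u, v, _ in edges}
    return len(orig_pairs & new_pairs) / len(orig_pairs)


def _double_edge_swaps(edges: list[tuple[str, str]], n_attempts: int,
                       rng: np.random.Generator,
                       forbidden: set[tuple[str, str]] = frozenset(),
                       ) -> list[tuple[str, str]]:
    """Maslov–Sneppen rewiring of an unweighted simple edge list.

    ``forbidden`` pairs (e.g. pairs occupied by the other sign subgraph)
    are never created, keeping the overall network simple.
    """
    if len(edges) < 2:
        return list(edges)
    edges = [tuple(sorted(e)) for e in edges]
    present = set(edges) | set(forbidden)
    m = len(edges)
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # two possible reconnections of the two chosen edges
        if rng.random() < 0.5:
            e1, e2 = (a, d), (c, b)
        else:
            e1, e2 = (a, c), (b, d)
        e1, e2 = tuple(sorted(e1)), tuple(sorted(e2))
        if e1[0] == e1[1] or e2[0] == e2[1] or e1 == e2:
            continue
        if (e1 in present and e1 not in (edges[i], edges[j])) or \
           (e2 in present and e2 not in (edges[i], edges[j])):
            continue
        present.discard(edges[i])
        present.discard(edges[j])
        edges[i], edges[j] = e1, e2
        present.add(e1)
        present.add(e2)
    return edges


def rewire_degree_preserving(network: CellLineSynergyNetwork, seed: int,
                             n_swaps_factor: float = DEFAULT_SWAP_FACTOR
                             ) -> RewireResult:
    """Degree-preserving (Maslov–Sneppen) randomization per sign subgraph.

    Every node keeps its positive-edge and negative-edge degree; weights of
    each sign are reassigned to that sign's new edges in random order.
    Sign subgraphs with fewer than two edges are returned unchanged.
    """
    if network.multi_edge_allowed:
        raise ValidationError("degree-preserving rewiring needs a simple network")
    rng = np.random.default_rng(seed)
    new_edges: list[tuple[str, str, float]] = []
    # rewire positive first against the original negative pairs, then
    # negative against the new positive pairs, so the result stays simple
    occupied = {(u, v) for u, v, _ in network.sign_subgraph(-1)}
    for sign in (+1, -1):
        sub = network.sign_subgraph(sign)
        if sign < 0:
            occupied = {(u, v) for u, v, _ in new_edges}
        if len(sub) < 2:
            new_edges.extend(sub)
            continue
        topo = _double_edge_swaps([(u, v) for u, v, _ in sub],
                                  int(n_swaps_factor * len(sub)), rng,
                                  forbidden=occupied)
        weights = np.array([w for _, _, w in sub])
        weights = weights[rng.permutation(len(weights))]
        new_edges.extend((u, v, float(w)) for (u, v), w in zip(topo, weights))
    rewired = CellLineSynergyNetwork(cell_line=network.cell_line,
                                     nodes=set(network.nodes), edges=new_edges)
    return RewireResult("degree_preserving", rewired, seed,
                        _retained_fraction(network, new_edges))


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling simulated-annealing schedule.

    The initial temperature is set from the dispersion of single-move
    energy changes sampled at the start; cooling multiplies it by
    ``cooling`` after each stage of ``moves_per_temperature`` proposals,
    stopping at the temperature floor or after ``patience`` stages without
    improvement of the best energy.
    """

    cooling: float = 0.9
    moves_per_temperature: int = 150
    t_floor_factor: float = 1e-6
    patience: int = 10
    max_stages: int = 100
    #: deterministic first-improvement passes after annealing
    refine_passes: int = 60
    #: annealing restarts for small subgraphs (rugged landscapes)
    restarts_small: int = 2
    small_edge_count: int = 80


class _SignAnnealer:
    """Anneal one sign subgraph toward the original strength sequence."""

    def __init__(self, nodes: list[str], edges: list[tuple[str, str, float]],
                 target_strength: dict[str, float], rng: np.random.Generator):
        self.rng = rng
        self.nodes = nodes
        self.edges = [(u, v) for u, v, _ in edges]
        self.weights = [w for _, _, w in edges]
        self.present = set(self.edges)
        self.target = target_strength
        self.s = {n: 0.0 for n in nodes}
        for (u, v), w in zip(self.edges, self.weights):
            self.s[u] += w
            self.s[v] += w
        self.energy = sum((self.target[n] - self.s[n]) ** 2 for n in nodes)
        self.best_energy = self.energy
        self.best_state = (list(self.edges), list(self.weights))

    def _delta(self, node: str, dw: float) -> float:
        cur = self.target[node] - self.s[node]
        return (cur - dw) ** 2 - cur ** 2

    def _propose_kind(self, i: int, j: int, kind: int) -> tuple[float, tuple] | None:
        """Evaluate one move: 0 = weight swap, 1/2 = the two double-edge
        swap reconnections (weights follow their first endpoint)."""
        (a, b), (c, d) = self.edges[i], self.edges[j]
        w1, w2 = self.weights[i], self.weights[j]
        if kind == 0:
            deltas: dict[str, float] = {}
            for n, dw in ((a, w2 - w1), (b, w2 - w1), (c, w1 - w2), (d, w1 - w2)):
                deltas[n] = deltas.get(n, 0.0) + dw
            de = sum(self._delta(n, dw) for n, dw in deltas.items())
            return de, ("wswap", i, j, deltas)
        if kind == 1:  # (a,b),(c,d) -> (a,d),(c,b)
            e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
            moved = ((b, w2 - w1), (d, w1 - w2))
        else:          # (a,b),(c,d) -> (a,c),(b,d)
            e1, e2 = tuple(sorted((a, c))), tuple(sorted((b, d)))
            moved = ((b, w2 - w1), (c, w1 - w2))
        if e1[0] == e1[1] or e2[0] == e2[1] or e1 == e2:
            return None
        if (e1 in self.present and e1 not in (self.edges[i], self.edges[j])) or \
           (e2 in self.present and e2 not in (self.edges[i], self.edges[j])):
            return None
        deltas = {}
        for n, dw in moved:
            deltas[n] = deltas.get(n, 0.0) + dw
        de = sum(self._delta(n, dw) for n, dw in deltas.items())
        return de, ("eswap", i, j, (e1, e2), deltas)

    def _propose(self) -> tuple[float, tuple] | None:
        m = len(self.edges)
        i, j = self.rng.integers(0, m, size=2)
        if i == j:
            return None
        return self._propose_kind(int(i), int(j), int(self.rng.integers(0, 3)))

    def _apply(self, de: float, move: tuple) -> None:
        kind, i, j = move[0], move[1], move[2]
        if kind == "wswap":
            deltas = move[3]
            self.weights[i], self.weights[j] = self.weights[j], self.weights[i]
        else:
            (e1, e2), deltas = move[3], move[4]
            self.present.discard(self.edges[i])
            self.present.discard(self.edges[j])
            self.edges[i], self.edges[j] = e1, e2
            self.present.add(e1)
            self.present.add(e2)
        for n, dw in deltas.items():
            self.s[n] += dw
        self.energy += de
        if self.energy < self.best_energy:
            self.best_energy = self.energy
            self.best_state = (list(self.edges), list(self.weights))

    def initial_temperature(self, n_samples: int = 50) -> float:
        des = []
        for _ in range(n_samples):
            prop = self._propose()
            if prop is not None:
                des.append(abs(prop[0]))
        return float(np.std(des) + np.mean(des)) if des else 1.0

    def run(self, schedule: AnnealSchedule) -> list[float]:
        if len(self.edges) < 2:
            return [self.best_energy]
        t = max(self.initial_temperature(), 1e-12)
        t_floor = t * schedule.t_floor_factor
        trace = [self.best_energy]
        stale = 0
        for _ in range(schedule.max_stages):
            improved = False
            for _ in range(schedule.moves_per_temperature):
                prop = self._propose()
                if prop is None:
                    continue
                de, move = prop
                if de <= 0 or self.rng.random() < math.exp(-de / t):
                    before = self.best_energy
                    self._apply(de, move)
                    if self.best_energy < before:
                        improved = True
            trace.append(self.best_energy)
            stale = 0 if improved else stale + 1
            t *= schedule.cooling
            if t < t_floor or stale >= schedule.patience or \
                    self.best_energy <= 1e-12:
                break
        self._greedy_refine(schedule.refine_passes)
        trace.append(self.best_energy)
        return trace

    def _greedy_refine(self, max_passes: int) -> None:
        """First-improvement local search from the best annealed state:
        sweep all edge pairs and move kinds, applying every improving move,
        until a local optimum (or the pass limit)."""
        self.edges, self.weights = (list(self.best_state[0]),
                                    list(self.best_state[1]))
        self.present = set(self.edges)
        self.s = {n: 0.0 for n in self.nodes}
        for (u, v), w in zip(self.edges, self.weights):
            self.s[u] += w
            self.s[v] += w
        self.energy = self.best_energy
        m = len(self.edges)
        for _ in range(max_passes):
            improved = False
            for i in range(m):
                for j in range(i + 1, m):
                    for kind in (0, 1, 2):
                        prop = self._propose_kind(i, j, kind)
                        if prop is not None and prop[0] < -1e-12:
                            self._apply(*prop)
                            improved = True
            if not improved or self.best_energy <= 1e-12:
                break


def rewire_strength_preserving(network: CellLineSynergyNetwork, seed: int,
                               schedule: AnnealSchedule = AnnealSchedule()
                               ) -> RewireResult:
    """Strength- and degree-preserving randomization via simulated annealing.

    Each sign subgraph starts from a degree-preserving rewiring and anneals
    toward the original per-node strength sequence of that sign under
    double-edge swaps and weight swaps; the best-energy state is returned.
    The recorded objective trace (best energy per cooling stage, summed
    over signs) is non-increasing.
    """
    if network.multi_edge_allowed:
        raise ValidationError("strength-preserving rewiring needs a simple network")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    new_edges: list[tuple[str, str, float]] = []
    traces: list[list[float]] = []
    for sign in (+1, -1):
        target = network.strength(sign=sign)
        orig_sub = network.sign_subgraph(sign)
        if len(orig_sub) < 2:
            new_edges.extend(orig_sub)
            continue
        n_attempts = (schedule.restarts_small
                      if len(orig_sub) <= schedule.small_edge_count else 1)
        best: _SignAnnealer | None = None
        trace: list[float] = []
        for _ in range(n_attempts):
            start = rewire_degree_preserving(network,
                                             seed=int(rng.integers(2**31)))
            annealer = _SignAnnealer(nodes, start.network.sign_subgraph(sign),
                                     target, rng)
            trace.extend(annealer.run(schedule))
            if best is None or annealer.best_energy < best.best_energy:
                best = annealer
            if best.best_energy <= 1e-12:
                break
        # running best across restarts keeps the reported trace monotone
        traces.append(list(np.minimum.accumulate(trace)))
        edges, weights = best.best_state
        new_edges.extend((u, v, float(w)) for (u, v), w in zip(edges, weights))
    length = max((len(t) for t in traces), default=1)
    trace = [sum(t[min(i, len(t) - 1)] for t in traces) for i in range(length)] \
        if traces else [0.0]
    rewired = CellLineSynergyNetwork(cell_line=network.cell_line,
                                     nodes=set(network.nodes), edges=new_edges,
                                     multi_edge_allowed=True)
    return RewireResult("strength_preserving", rewired, seed,
                        _retained_fraction(network, new_edges),
                        objective_trace=trace)


def permute_edge_weights(network: CellLineSynergyNetwork, seed: int) -> RewireResult:
    """Keep every edge, permute the weights within each sign class."""
    rng = np.random.default_rng(seed)
    new_edges: list[tuple[str, str, float]] = []
    for sign in (+1, -1):
        sub = network.sign_subgraph(sign)
        weights = np.array([w for _, _, w in sub])
        weights = weights[rng.permutation(len(weights))] if len(sub) else weights
        new_edges.extend((u, v, float(w)) for (u, v, _), w in zip(sub, weights))
    rewired = CellLineSynergyNetwork(cell_line=network.cell_line,
                                     nodes=set(network.nodes), edges=new_edges,
                                     multi_edge_allowed=network.multi_edge_allowed)
    return RewireResult("weight_permutation", rewired, seed, 1.0)


_METHODS = {
    "degree_preserving": rewire_degree_preserving,
    "strength_preserving": rewire_strength_preserving,
    "weight_permutation": permute_edge_weights,
}


def rewire_training_table(table: TripletTable, split: DataSplit, method: str,
                          seed: int, **kwargs) -> tuple[TripletTable, list[RewireResult]]:
    """Rewire the training partition's per-cell-line networks and reassemble
    a training table from the union of the rewired networks.

    Where strength-preserving rewiring leaves both a positive and a
    negative edge on one pair, the two weights are summed into a single
    training triplet (a triplet table holds one score per key).
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown rewiring method {method!r}")
    train_table = table.subset(split.train)
    networks = build_cell_line_networks(train_table)
    rng = np.random.default_rng(seed)
    results = []
    triplets = []
    for cell, net in sorted(networks.items()):
        res = _METHODS[method](net, seed=int(rng.integers(2**31)), **kwargs)
        results.append(res)
        merged: dict[tuple[str, str], float] = {}
        for u, v, w in res.network.edges:
            merged[(u, v)] = merged.get((u, v), 0.0) + w
        for (u, v), w in sorted(merged.items()):
            triplets.append(SynergyTriplet.make(u, v, cell, w))
    rewired_table = TripletTable(triplets, drug_universe=table.drug_universe,
                                 cell_line_universe=table.cell_line_universe)
    return rewired_table, results


def build_training_variant(table: TripletTable, split: DataSplit,
                           variant: str, seed: int = 0,
                           stores: Mapping[str, FeatureStore] | None = None,
                           shuffle_store: str | None = None,
                           rewire_method: str | None = None,
                           ) -> tuple[TripletTable, DataSplit,
                                      Mapping[str, FeatureStore] | None]:
    """Assemble training inputs for an ablation variant.

    ``original`` is the identity; ``shuffled_features`` returns the stores
    with ``shuffle_store`` permuted; ``rewired`` replaces the training
    partition with a randomized version.  Validation and test triplets and
    scores are always the originals.
    """
    if variant == "original":
        return table, split, stores
    if variant == "shuffled_features":
        if stores is None or shuffle_store is None:
            raise ValidationError("shuffled_features needs stores and a store name")
        new_stores = dict(stores)
        new_stores[shuffle_store] = shuffle_features(stores[shuffle_store], seed)
        return table, split, new_stores
    if variant == "rewired":
        if rewire_method is None:
            raise ValidationError("rewired variant needs a rewire_method")
        rewired_train, _ = rewire_training_table(table, split, rewire_method, seed)
        # evaluation partitions keep their original triplets and scores; a
        # rewired training edge that collides with an evaluation key is
        # dropped (a table holds one score per key)
        eval_keys = {table[i].key for i in split.validation + split.test}
        train_triplets = [t for t in rewired_train if t.key not in eval_keys]
        val_triplets = [table[i] for i in split.validation]
        test_triplets = [table[i] for i in split.test]
        new_table = TripletTable(train_triplets + val_triplets + test_triplets,
                                 drug_universe=table.drug_universe,
                                 cell_line_universe=table.cell_line_universe)
        n_tr, n_val = len(train_triplets), len(val_triplets)
        new_split = DataSplit(split.strategy,
                              list(range(n_tr)),
                              list(range(n_tr, n_tr + n_val)),
                              list(range(n_tr + n_val, len(new_table))),
                              seed=split.seed, fractions=split.fractions,
                              strict_leave_drug=split.strict_leave_drug)
        return new_table, new_split, stores
    raise ValidationError(f"unknown variant {variant!r}")
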