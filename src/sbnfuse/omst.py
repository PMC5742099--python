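"""Topological filtering by orthogonal minimum spanning trees (OMST).

Dense weighted networks are filtered by repeatedly extracting edge-disjoint
minimum spanning trees (on distances 1/weight, so each round captures the
strongest backbone still available), accumulating the rounds, and keeping
the prefix that maximizes global cost efficiency

    J = GE - Cost

where GE is the weighted global efficiency of the selected subgraph
(max-normalized weights, so J is invariant to the weight scale) and Cost
is the selected fraction of total edge weight.
Round 1 alone is a spanning tree, so the filtered network is connected by
construction whenever the input is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import global_efficiency
from .network import WeightedNetwork
from .synthetic import InvalidParameterError

Edge = tuple[int, int]


class EdgelessGraphError(ValueError):
    pass


@dataclass
class OmstResult:
    """Outcome of the OMST filter.

    ``curve`` has one row per cumulative round: (round, cost, GE, J).
    ``n_rounds`` is the prefix chosen at the J peak; ``filtered`` keeps the
    original weights on the selected edges and zeros elsewhere.
    """

    selected_edges: list[Edge]
    n_rounds: int
    curve: np.ndarray
    filtered: WeightedNetwork
    rounds: list[list[Edge]]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _sorted_edges(w: np.ndarray) -> list[tuple[float, int, int]]:
    iu, ju = np.triu_indices(w.shape[0], 1)
    mask = w[iu, ju] > 0
    iu, ju = iu[mask], ju[mask]
    dist = 1.0 / w[iu, ju]
    order = np.lexsort((ju, iu, dist))  # distance, then (i, j) lexicographic
    return [(dist[k], int(iu[k]), int(ju[k])) for k in order]


def minimum_spanning_forest(W: WeightedNetwork | np.ndarray,
                            exclude: set[Edge] | None = None) -> list[Edge]:
    """Kruskal's minimum spanning forest on distances 1/weight.

    Ties break deterministically by (distance, i, j).  ``exclude`` removes
    edges already claimed by earlier rounds.  Returns a spanning tree per
    connected component of the remaining graph.
    """
    w = W.weights if isinstance(W, WeightedNetwork) else np.asarray(W, dtype=float)
    exclude = exclude or set()
    uf = _UnionFind(w.shape[0])
    forest: list[Edge] = []
    for _, i, j in _sorted_edges(w):
        if (i, j) in exclude:
            continue
        if uf.union(i, j):
            forest.append((i, j))
    return forest


def orthogonal_msts(W: WeightedNetwork, max_rounds: int | None = None) -> list[list[Edge]]:
    """Successive edge-disjoint minimum spanning forests.

    Round r runs Kruskal on the graph minus all edges selected in rounds
    1..r-1; extraction stops when no edges remain (every observed weight
    has been tested) or after ``max_rounds``.
    """
    if max_rounds is not None and max_rounds < 1:
        raise InvalidParameterError("max_rounds must be >= 1")
    taken: set[Edge] = set()
    rounds: list[list[Edge]] = []
    n_edges = W.n_edges
    while len(taken) < n_edges and (max_rounds is None or len(rounds) < max_rounds):
        forest = minimum_spanning_forest(W, exclude=taken)
        if not forest:
            break
        rounds.append(forest)
        taken.update(forest)
    return rounds


def _subgraph(W: WeightedNetwork, edges: list[Edge]) -> WeightedNetwork:
    sub = np.zeros_like(W.weights)
    for i, j in edges:
        sub[i, j] = sub[j, i] = W.weights[i, j]
    return WeightedNetwork(sub, list(W.node_labels))


def omst_filter(W: WeightedNetwork, max_rounds: int | None = None) -> OmstResult:
    """Filter ``W`` to the cumulative OMST prefix maximizing GE - Cost.

    Cost is the summed weight of selected edges over the total weight of
    the input.  GE is evaluated on max-normalized weights so that both
    terms of J are scale-invariant and GE lies in [0, 1]; the returned
    ``filtered`` network keeps the original weights.  Ties on J prefer
    fewer rounds.  The full (round, cost, GE, J) curve is reported for
    diagnostics.
    """
    total = np.triu(W.weights, 1).sum()
    if total <= 0:
        raise EdgelessGraphError("cannot filter a network with no edges")
    rounds = orthogonal_msts(W, max_rounds=max_rounds)
    scaled = W.max_normalized()

    curve = np.zeros((len(rounds), 4))
    cumulative: list[Edge] = []
    best_j, best_r = -np.inf, 0
    selected_at_best: list[Edge] = []
    for r, forest in enumerate(rounds, start=1):
        cumulative = cumulative + forest
        cost = sum(W.weights[i, j] for i, j in cumulative) / total
        ge = global_efficiency(_subgraph(scaled, cumulative))
        j_val = ge - cost
        curve[r - 1] = (r, cost, ge, j_val)
        if j_val > best_j:  # strict: ties keep the earlier (sparser) prefix
            best_j, best_r = j_val, r
            selected_at_best = list(cumulative)

    filtered = _subgraph(W, selected_at_best)
    return OmstResult(selected_edges=selected_at_best, n_rounds=best_r,
                      curve=curve, filtered=filtered, rounds=rounds)
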