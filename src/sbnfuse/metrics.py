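"""Graph-theoretic summary metrics on weighted networks.

Edge weights are connection strengths; path computations use the standard
weighted-connectome convention distance = 1/weight, so the strongest
connections are the shortest.  Unreachable pairs contribute zero to
efficiency; characteristic path length and eccentricities are computed on
the largest connected component (with a warning) when the graph is
disconnected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra

from .network import WeightedNetwork
from .synthetic import InvalidParameterError


def shortest_paths(W: WeightedNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths over edge distances 1/weight.

    Unreachable pairs are +inf; the diagonal is 0.
    """
    w = W.weights if isinstance(W, WeightedNetwork) else np.asarray(W, dtype=float)
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(dist, directed=False)


def _inv_dist(sp: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(sp)
    finite = np.isfinite(sp) & (sp > 0)
    inv[finite] = 1.0 / sp[finite]
    return inv


def global_efficiency(W: WeightedNetwork) -> float:
    """Mean over ordered node pairs of 1/shortest-path-distance."""
    if W.n < 2:
        raise InvalidParameterError("efficiency needs at least 2 nodes")
    inv = _inv_dist(shortest_paths(W))
    n = W.n
    return float(inv.sum() / (n * (n - 1)))

def node_global_efficiency(W: WeightedNetwork) -> np.ndarray:
    """Per node: mean of 1/distance to every other node."""
    if W.n < 2:
        raise InvalidParameterError("efficiency needs at least 2 nodes")
    inv = _inv_dist(shortest_paths(W))
    return inv.sum(axis=1) / (W.n - 1)


def node_local_efficiency(W: WeightedNetwork) -> np.ndarray:
    """Per node: global efficiency of the subgraph induced by its neighbors.

    Nodes with fewer than two neighbors score zero.
    """
    w = W.weights
    out = np.zeros(W.n)
    for i in range(W.n):
        nbrs = np.flatnonzero(w[i] > 0)
        if len(nbrs) < 2:
            continue
        sub = WeightedNetwork(w[np.ix_(nbrs, nbrs)],
                              [W.node_labels[k] for k in nbrs])
        out[i] = global_efficiency(sub)
    return out


def local_efficiency(W: WeightedNetwork) -> float:
    """Mean node-level local efficiency."""
    return float(node_local_efficiency(W).mean())


def path_summaries(W: WeightedNetwork) -> tuple[float, np.ndarray, float, float]:
    """Characteristic path length, node eccentricities, radius, diameter.

    On disconnected graphs these are computed within the largest connected
    component; eccentricities of nodes outside it are NaN.
    """
    w = W.weights
    n_comp, labels = connected_components(w > 0, directed=False)
    sp = shortest_paths(W)
    ecc = np.full(W.n, np.nan)
    if n_comp > 1:
        sizes = np.bincount(labels)
        if sizes.max() < 2:
            raise InvalidParameterError("graph has no connected pair of nodes")
        warnings.warn(f"graph has {n_comp} components; path summaries use the largest")
        keep = np.flatnonzero(labels == sizes.argmax())
    else:
        keep = np.arange(W.n)
    sub = sp[np.ix_(keep, keep)]
    m = len(keep)
    cpl = float(sub.sum() / (m * (m - 1)))
    ecc[keep] = sub.max(axis=1)
    radius = float(np.nanmin(ecc))
    diameter = float(np.nanmax(ecc))
    return cpl, ecc, radius, diameter


def mean_strength(W: WeightedNetwork) -> float:
    """Mean node strength (mean row sum of the adjacency)."""
    return float(W.strengths().mean())


#: Network-level metric names in reporting order.
NETWORK_METRICS = ("GE", "LE", "CPL", "ECC", "radius", "diameter", "STR")


@dataclass
class MetricRecord:
    """All network- and node-level metrics of one scan's network."""

    scan_id: str
    subject_id: str
    variant: str                 # which network: a weighting strategy, fused, filtered...
    network_level: dict[str, float]
    node_ge: np.ndarray
    node_le: np.ndarray


def compute_metrics(W: WeightedNetwork, scan_id: str = "", subject_id: str = "",
                    variant: str = "") -> MetricRecord:
    """Evaluate the full metric battery on one network."""
    cpl, ecc, radius, diameter = path_summaries(W)
    node_ge = node_global_efficiency(W)
    node_le = node_local_efficiency(W)
    network_level = {
        "GE": global_efficiency(W),
        "LE": float(node_le.mean()),
        "CPL": cpl,
        "ECC": float(np.nanmean(ecc)),
        "radius": radius,
        "diameter": diameter,
        "STR": mean_strength(W),
    }
    return MetricRecord(scan_id, subject_id, variant, network_level, node_ge, node_le)
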