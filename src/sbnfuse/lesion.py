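"""Virtual lesion (network attack) schemes and per-node influence weights.

Each node (or cluster of nodes) is attacked in one of three ways —
zeroing the strongest half of its connections, halving all of them, or
both combined — and the diffusion distance between the original and the
lesioned network measures how much that node carries the network's
information flow.  The resulting per-node (or per-cluster) distances,
normalized to sum one, form a linear weight vector.

"Half of the connections" is the strongest floor(m/2) incident edges by
weight, with deterministic (weight, neighbor-index) tie-breaking; a
seeded random choice is available as an alternative.
"""

from __future__ import annotations

import warnings

import numpy as np
import networkx as nx

from .gddm import GddmOptions, gddm_distance
from .network import WeightedNetwork
from .synthetic import InvalidParameterError

LESION_SCHEMES = ("zero_half", "diminish_half", "combined")
CLUSTER_TARGETS = ("within_rc", "within_nonrc", "between")


def _half_split(w_row: np.ndarray, node: int, rng: np.random.Generator | None):
    """Split a node's neighbors into (strongest half, rest)."""
    nbrs = np.flatnonzero(w_row > 0)
    n_half = len(nbrs) // 2
    if rng is not None:
        chosen = rng.choice(nbrs, size=n_half, replace=False)
        return np.sort(chosen), np.setdiff1d(nbrs, chosen)
    # strongest first; ties by neighbor index
    order = np.lexsort((nbrs, -w_row[nbrs]))
    strong = np.sort(nbrs[order[:n_half]])
    weak = np.sort(nbrs[order[n_half:]])
    return strong, weak


def node_attack(W: WeightedNetwork, node: int, scheme: str,
                rng: np.random.Generator | None = None) -> WeightedNetwork:
    """Lesion one node's connections; output remains symmetric.

    ``zero_half``: strongest half of incident edges removed.
    ``diminish_half``: every incident edge halved.
    ``combined``: strongest half removed, the rest halved.
    """
    if scheme not in LESION_SCHEMES:
        raise InvalidParameterError(f"scheme must be one of {LESION_SCHEMES}")
    if not 0 <= node < W.n:
        raise InvalidParameterError(f"node {node} out of range")
    w = W.weights.copy()
    nbrs = np.flatnonzero(w[node] > 0)
    if len(nbrs) == 0:
        warnings.warn(f"node {node} is isolated; attack is a no-op")
        return WeightedNetwork(w, list(W.node_labels))
    if scheme == "diminish_half":
        w[node, nbrs] *= 0.5
        w[nbrs, node] *= 0.5
        return WeightedNetwork(w, list(W.node_labels))
    if len(nbrs) < 2:
        raise InvalidParameterError("half-splitting needs a node with >= 2 connections")
    strong, weak = _half_split(W.weights[node], node, rng)
    w[node, strong] = 0.0
    w[strong, node] = 0.0
    if scheme == "combined":
        w[node, weak] *= 0.5
        w[weak, node] *= 0.5
    return WeightedNetwork(w, list(W.node_labels))


def node_lesion_weights(W: WeightedNetwork, scheme: str = "combined",
                        options: GddmOptions | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-node influence: gDDM(original, node-lesioned), normalized to sum 1."""
    dists = np.zeros(W.n)
    for node in range(W.n):
        lesioned = node_attack(W, node, scheme, rng=rng)
        dists[node], _ = gddm_distance(W, lesioned, options)
    total = dists.sum()
    if total == 0:
        warnings.warn("all lesion distances are zero; falling back to uniform weights")
        return np.full(W.n, 1.0 / W.n)
    return dists / total


def partition_clusters(W: WeightedNetwork, method: str = "modularity") -> np.ndarray:
    """Cluster the nodes for cluster-wise attacks.

    ``modularity``: greedy weighted modularity maximization; returns
    integer module ids.  ``richclub``: hubs are nodes with strength above
    mean + 1 SD; hubs whose within-hub strength exceeds the median
    within-hub strength of hubs are rich-club hubs.  Returns an object
    array of labels in {"rc_hub", "hub", "non_hub"}.
    """
    if W.n < 4:
        raise InvalidParameterError("need at least 4 nodes to partition")
    if method == "modularity":
        g = nx.from_numpy_array(W.weights)
        comms = nx.community.greedy_modularity_communities(g, weight="weight")
        labels = np.zeros(W.n, dtype=int)
        for cid, members in enumerate(comms):
            labels[list(members)] = cid
        return labels
    if method == "richclub":
        s = W.strengths()
        hub_mask = s > s.mean() + s.std()
        labels = np.array(["non_hub"] * W.n, dtype=object)
        hubs = np.flatnonzero(hub_mask)
        if len(hubs) > 0:
            labels[hubs] = "hub"
            within = W.weights[np.ix_(hubs, hubs)].sum(axis=1)
            if len(hubs) > 1:
                rc = hubs[within > np.median(within)]
                labels[rc] = "rc_hub"
        return labels
    raise InvalidParameterError("method must be 'modularity' or 'richclub'")


def _edge_class_mask(labels: np.ndarray, target: str) -> np.ndarray:
    rc = labels == "rc_hub"
    if target == "within_rc":
        return np.outer(rc, rc)
    if target == "within_nonrc":
        return np.outer(~rc, ~rc)
    if target == "between":
        return np.outer(rc, ~rc) | np.outer(~rc, rc)
    raise InvalidParameterError(f"target must be one of {CLUSTER_TARGETS}")


def cluster_attack(W: WeightedNetwork, labels: np.ndarray, scheme: str,
                   target: str) -> WeightedNetwork:
    """Apply a lesion scheme to one class of edges (rich-club partition).

    ``target`` selects edges within rich-club hubs, within everything
    else, or between the two groups; the scheme then zeroes/halves the
    strongest half (by weight over the whole class) or all of them.
    """
    if scheme not in LESION_SCHEMES:
        raise InvalidParameterError(f"scheme must be one of {LESION_SCHEMES}")
    labels = np.asarray(labels, dtype=object)
    mask = _edge_class_mask(labels, target) & (W.weights > 0)
    np.fill_diagonal(mask, False)
    w = W.weights.copy()
    iu, ju = np.where(np.triu(mask, 1))
    if len(iu) == 0:
        warnings.warn(f"edge class '{target}' is empty; attack is a no-op")
        return WeightedNetwork(w, list(W.node_labels))
    if scheme == "diminish_half":
        w[iu, ju] *= 0.5
        w[ju, iu] *= 0.5
        return WeightedNetwork(w, list(W.node_labels))
    vals = W.weights[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    n_half = len(iu) // 2
    strong = order[:n_half]
    weak = order[n_half:]
    w[iu[strong], ju[strong]] = 0.0
    w[ju[strong], iu[strong]] = 0.0
    if scheme == "combined":
        w[iu[weak], ju[weak]] *= 0.5
        w[ju[weak], iu[weak]] *= 0.5
    return WeightedNetwork(w, list(W.node_labels))


def cluster_lesion_weights(W: WeightedNetwork, labels: np.ndarray,
                           scheme: str = "combined",
                           targets: tuple[str, ...] = CLUSTER_TARGETS,
                           options: GddmOptions | None = None) -> dict[str, float]:
    """Per-edge-class influence weights, normalized to sum 1."""
    dists = {}
    for target in targets:
        lesioned = cluster_attack(W, labels, scheme, target)
        dists[target], _ = gddm_distance(W, lesioned, options)
    total = sum(dists.values())
    if total == 0:
        warnings.warn("all cluster lesion distances are zero; uniform weights")
        return {t: 1.0 / len(targets) for t in targets}
    return {t: d / total for t, d in dists.items()}


def node_weighted_stack(stack, scheme: str = "combined",
                        options: GddmOptions | None = None):
    """Rescale every network in a stack node-wise by its lesion weights.

    Edge (i, j) is multiplied by sqrt(v_i * v_j) of the normalized lesion
    vector v, keeping the matrix symmetric.  This is the optional
    node-level weighting step placed before network-level fusion.
    """
    from .nws import NwsStack  # local import to avoid cycle

    out = {}
    for name, net in stack.networks.items():
        v = node_lesion_weights(net, scheme=scheme, options=options)
        scale = np.sqrt(np.outer(v, v))
        out[name] = WeightedNetwork(net.weights * scale, list(net.node_labels))
    return NwsStack(scan_id=stack.scan_id, subject_id=stack.subject_id, networks=out)
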