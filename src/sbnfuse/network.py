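"""Core container for undirected weighted networks.

All graphs in this package are undirected, nonnegatively weighted networks
over a fixed node set (typically parcellation regions of interest).  The
adjacency matrix is the single source of truth: symmetric, zero diagonal,
finite, nonnegative.  A zero entry means "no connection".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidNetworkError(ValueError):
    """Raised when a matrix violates the weighted-network contract."""


def validate_weights(weights: np.ndarray, *, atol: float = 1e-9) -> np.ndarray:
    """Validate and canonicalize an adjacency matrix.

    Checks squareness, finiteness, nonnegativity, symmetry (within ``atol``)
    and zeroes the diagonal.  Returns a float64 copy.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidNetworkError(f"adjacency matrix must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        bad = np.argwhere(~np.isfinite(w))[0]
        raise InvalidNetworkError(f"non-finite weight at cell ({bad[0]}, {bad[1]})")
    if np.any(w < 0):
        bad = np.argwhere(w < 0)[0]
        raise InvalidNetworkError(f"negative weight at cell ({bad[0]}, {bad[1]})")
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > atol:
        i, j = np.unravel_index(np.abs(w - w.T).argmax(), w.shape)
        raise InvalidNetworkError(f"asymmetric beyond tolerance at cell ({i}, {j}): |w_ij - w_ji| = {asym:g}")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


@dataclass
class WeightedNetwork:
    """A symmetric, nonnegative weighted graph with labelled nodes.

    Parameters
    ----------
    weights
        Square symmetric matrix of nonnegative edge weights; the diagonal
        is forced to zero.
    node_labels
        Optional node names; defaults to ``roi_1 ... roi_n``.
    """

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = validate_weights(self.weights)
        n = self.weights.shape[0]
        if not self.node_labels:
            self.node_labels = [f"roi_{i + 1}" for i in range(n)]
        if len(self.node_labels) != n:
            raise InvalidNetworkError(
                f"{len(self.node_labels)} labels for {n} nodes"
            )

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero undirected edges."""
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def density(self) -> float:
        """Fraction of possible undirected edges that are present."""
        n = self.n
        return self.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0

    def strengths(self) -> np.ndarray:
        """Node strengths (weighted degrees): row sums of the adjacency."""
        return self.weights.sum(axis=1)

    def max_normalized(self) -> "WeightedNetwork":
        """Rescale weights to [0, 1] by the largest entry (no-op if empty)."""
        m = self.weights.max()
        w = self.weights / m if m > 0 else self.weights.copy()
        return WeightedNetwork(w, list(self.node_labels))

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.weights.copy(), list(self.node_labels))
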