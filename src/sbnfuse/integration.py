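"""Linear fusion of the nine weighted networks into one integrated network.

For a single scan, the nine weighting strategies are compared pairwise
with the graph diffusion distance; the row sums of the resulting 9 x 9
dissimilarity matrix, normalized to total one, become linear weights, and
the integrated network is the corresponding convex combination of the
(rescaled) strategy matrices.  Row-sum weighting gives more weight to
strategies that are more dissimilar from the rest; an inverse mode
(weights proportional to 1/row-sum) is available but not the default.
"""

from __future__ import annotations

import warnings

import numpy as np

from .gddm import DissimilarityMatrix, GddmOptions, pairwise_dissimilarity
from .network import WeightedNetwork
from .nws import NWS_NAMES, NWS_TRIADS, NwsStack
from .synthetic import InvalidParameterError

PRESCALE_MODES = ("max", "none")


class DegenerateDissimilarityError(ValueError):
    """All pairwise distances are zero: the inputs are indistinguishable."""


def integration_weights(D: DissimilarityMatrix | np.ndarray,
                        mode: str = "rowsum") -> np.ndarray:
    """Linear weights from a dissimilarity matrix: normalized row sums.

    ``mode='inverse'`` uses normalized reciprocal row sums instead, so
    strategies closest to the consensus weigh most.
    """
    d = D.D if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidParameterError("dissimilarity matrix must be square")
    rowsums = d.sum(axis=1)
    if rowsums.sum() == 0:
        raise DegenerateDissimilarityError("all dissimilarities are zero; weights undefined")
    if mode == "inverse":
        inv = 1.0 / np.where(rowsums > 0, rowsums, np.inf)
        if inv.sum() == 0:
            raise DegenerateDissimilarityError("inverse weights undefined")
        return inv / inv.sum()
    if mode != "rowsum":
        raise InvalidParameterError("mode must be 'rowsum' or 'inverse'")
    return rowsums / rowsums.sum()


def _prescale(W: WeightedNetwork, mode: str) -> WeightedNetwork:
    if mode == "max":
        return W.max_normalized()
    if mode == "none":
        return W
    raise InvalidParameterError(f"prescale mode must be one of {PRESCALE_MODES}")


def integrate(stack: NwsStack | dict[str, WeightedNetwork],
              l_w: dict[str, float] | np.ndarray,
              prescale_mode: str = "max",
              names: tuple[str, ...] = NWS_NAMES) -> WeightedNetwork:
    """Weighted sum of the (prescaled) strategy networks.

    ``l_w`` is keyed by strategy name, or an array aligned with ``names``.
    """
    nets = stack.networks if isinstance(stack, NwsStack) else stack
    if isinstance(l_w, dict):
        if set(l_w) != set(names):
            raise InvalidParameterError(f"weight keys {set(l_w)} do not match {set(names)}")
        w_vec = np.array([l_w[k] for k in names], dtype=float)
    else:
        w_vec = np.asarray(l_w, dtype=float)
        if w_vec.shape != (len(names),):
            raise InvalidParameterError(f"expected {len(names)} weights, got {w_vec.shape}")
    missing = set(names) - set(nets)
    if missing:
        raise InvalidParameterError(f"stack lacks networks {missing}")
    if np.any(w_vec < 0):
        raise InvalidParameterError("integration weights must be nonnegative")

    scaled = [_prescale(nets[k], prescale_mode) for k in names]
    acc = np.zeros_like(scaled[0].weights)
    for wk, net in zip(w_vec, scaled):
        acc += wk * net.weights
    return WeightedNetwork(acc, list(scaled[0].node_labels))


def integrate_scan(stack: NwsStack,
                   prescale_mode: str = "max",
                   gddm_options: GddmOptions | None = None,
                   weight_mode: str = "rowsum",
                   names: tuple[str, ...] = NWS_NAMES,
                   ) -> tuple[WeightedNetwork, np.ndarray, DissimilarityMatrix]:
    """Full per-scan fusion: dissimilarities -> weights -> integrated network.

    Prescaling is applied before both the distance computation and the
    summation.  A fully degenerate dissimilarity matrix (all strategies
    identical) falls back to uniform weights with a warning.

    Returns ``(integrated, weights, dissimilarity)``.
    """
    nets = [_prescale(stack[k], prescale_mode) for k in names]
    D = pairwise_dissimilarity(nets, labels=list(names), options=gddm_options)
    try:
        w = integration_weights(D, mode=weight_mode)
    except DegenerateDissimilarityError:
        warnings.warn("all pairwise dissimilarities are zero; using uniform weights")
        w = np.full(len(names), 1.0 / len(names))
    fused = integrate(stack, w, prescale_mode=prescale_mode, names=names)
    return fused, w, D


def triad_integration(stack: NwsStack,
                      triads: tuple[tuple[str, str, str], ...] = NWS_TRIADS,
                      prescale_mode: str = "max",
                      gddm_options: GddmOptions | None = None,
                      ) -> dict[tuple[str, ...], WeightedNetwork]:
    """Apply the fusion independently to each triad of strategies."""
    out: dict[tuple[str, ...], WeightedNetwork] = {}
    for triad in triads:
        missing = set(triad) - set(stack.networks)
        if missing:
            raise InvalidParameterError(f"incomplete triad {triad}: missing {missing}")
        fused, _, _ = integrate_scan(stack, prescale_mode=prescale_mode,
                                     gddm_options=gddm_options, names=tuple(triad))
        out[tuple(triad)] = fused
    return out
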