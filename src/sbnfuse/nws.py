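"""Build the nine weighted structural brain networks from a tract table.

Given a per-scan table of ROI-pair streamline aggregates plus parcellation
geometry, this module assembles one symmetric connectivity matrix per
weighting strategy:

======  ==============================================================
FA      streamline-count-weighted mean fractional anisotropy
MD      streamline-count-weighted mean mean-diffusivity
RD      streamline-count-weighted mean radial diffusivity
ATL     streamline-count-weighted mean tract length (mm)
ED      Euclidean distance between ROI centroids (mm, fully dense)
SD      streamline density corrected for ROI size:
        w_ij = 2 / (g_i + g_j) * |S_ij|, g = gray-matter voxel count
TV      summed tract volume (mm^3)
NSTR    number of streamlines
PSTR    NSTR normalized by total streamline count across the network
======  ==============================================================

Records can first be filtered by minimum contiguous white-matter length,
the standard guard against spurious short tracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import WeightedNetwork
from .synthetic import InvalidParameterError, RoiGeometry

#: Canonical ordering of the nine weighting strategies.
NWS_NAMES = ("FA", "MD", "RD", "ATL", "ED", "SD", "TV", "NSTR", "PSTR")

#: The three conventional triads: tensor metrics, geometry/density, streamline counts.
NWS_TRIADS = (("FA", "MD", "RD"), ("ATL", "SD", "ED"), ("NSTR", "PSTR", "TV"))


class EmptyNetworkError(ValueError):
    """No records survive filtering, so count-based weights are undefined."""


@dataclass
class NwsStack:
    """The nine labelled networks of a single scan."""

    scan_id: str
    subject_id: str
    networks: dict[str, WeightedNetwork] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.networks) != set(NWS_NAMES):
            missing = set(NWS_NAMES) - set(self.networks)
            extra = set(self.networks) - set(NWS_NAMES)
            raise InvalidParameterError(f"stack must hold exactly {NWS_NAMES}; missing={missing}, extra={extra}")
        ns = {w.n for w in self.networks.values()}
        if len(ns) != 1:
            raise InvalidParameterError(f"inconsistent node counts across stack: {ns}")

    @property
    def n(self) -> int:
        return next(iter(self.networks.values())).n

    def __getitem__(self, name: str) -> WeightedNetwork:
        return self.networks[name]

    def ordered(self, names: tuple[str, ...] = NWS_NAMES) -> list[WeightedNetwork]:
        return [self.networks[k] for k in names]


def threshold_grid(start_mm: float, stop_mm: float, step_mm: float) -> np.ndarray:
    """Inclusive arithmetic grid of length thresholds, e.g. 0..6 mm by 0.5."""
    if step_mm <= 0:
        raise InvalidParameterError("step must be positive")
    if stop_mm < start_mm:
        raise InvalidParameterError("stop must be >= start")
    n = int(np.floor((stop_mm - start_mm) / step_mm + 1e-9)) + 1
    return start_mm + step_mm * np.arange(n)


def length_filter(table: pd.DataFrame, l_mm: float) -> pd.DataFrame:
    """Discard tracts whose contiguous white-matter length is below ``l_mm``."""
    if l_mm < 0:
        raise InvalidParameterError("length threshold must be nonnegative")
    if l_mm == 0:
        return table
    return table[table["wm_length_mm"] >= l_mm]


def sd_weight(g_i: int, g_j: int, n_streamlines: int) -> float:
    """Streamline density corrected for ROI size: 2/(g_i+g_j) * |S_ij|."""
    if g_i < 1 or g_j < 1:
        raise InvalidParameterError("voxel counts must be >= 1")
    if n_streamlines < 0:
        raise InvalidParameterError("streamline count must be nonnegative")
    return 2.0 / (g_i + g_j) * n_streamlines


def ed_matrix(geometry: RoiGeometry) -> WeightedNetwork:
    """Dense matrix of pairwise Euclidean distances between ROI centroids."""
    if geometry.n_rois < 2:
        raise InvalidParameterError("need at least 2 ROIs")
    c = geometry.centroids
    diff = c[:, None, :] - c[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    return WeightedNetwork(d, list(geometry.roi_labels))


def build_nws(table: pd.DataFrame, geometry: RoiGeometry, l_mm: float = 0.0,
              scan_id: str = "", subject_id: str = "") -> NwsStack:
    """Aggregate a tract table into the nine connectivity matrices.

    Multiple records for the same ROI pair are merged: counts and volumes
    add; FA/MD/RD/ATL combine as streamline-count-weighted means.
    """
    filtered = length_filter(table, l_mm)
    if len(filtered) == 0:
        raise EmptyNetworkError(f"no tracts survive the {l_mm} mm length threshold")
    n = geometry.n_rois
    i = filtered["roi_i"].to_numpy(dtype=int)
    j = filtered["roi_j"].to_numpy(dtype=int)
    if np.any(i == j):
        raise InvalidParameterError("self-connection record (roi_i == roi_j)")
    if i.min() < 0 or j.min() < 0 or max(i.max(), j.max()) >= n:
        raise InvalidParameterError("ROI index out of range for geometry")

    counts = filtered["n_streamlines"].to_numpy(dtype=float)

    def accumulate(values: np.ndarray) -> np.ndarray:
        m = np.zeros((n, n))
        np.add.at(m, (i, j), values)
        np.add.at(m, (j, i), values)
        return m

    nstr = accumulate(counts)
    tv = accumulate(filtered["tract_volume_mm3"].to_numpy(dtype=float))

    # count-weighted means for the per-streamline-bundle metrics
    means = {}
    for name, col in (("FA", "mean_fa"), ("MD", "mean_md"), ("RD", "mean_rd"),
                      ("ATL", "mean_length_mm")):
        num = accumulate(counts * filtered[col].to_numpy(dtype=float))
        with np.errstate(invalid="ignore"):
            means[name] = np.where(nstr > 0, num / np.where(nstr > 0, nstr, 1.0), 0.0)

    total = np.triu(nstr, 1).sum()
    pstr = nstr / total

    g = geometry.voxel_counts.astype(float)
    sd = (2.0 / (g[:, None] + g[None, :])) * nstr

    labels = list(geometry.roi_labels)
    networks = {
        "FA": WeightedNetwork(means["FA"], labels),
        "MD": WeightedNetwork(means["MD"], labels),
        "RD": WeightedNetwork(means["RD"], labels),
        "ATL": WeightedNetwork(means["ATL"], labels),
        "ED": ed_matrix(geometry),
        "SD": WeightedNetwork(sd, labels),
        "TV": WeightedNetwork(tv, labels),
        "NSTR": WeightedNetwork(nstr, labels),
        "PSTR": WeightedNetwork(pstr, labels),
    }
    if not scan_id and "scan_id" in filtered.columns and len(filtered):
        scan_id = str(filtered["scan_id"].iloc[0])
    if not subject_id and "subject_id" in filtered.columns and len(filtered):
        subject_id = str(filtered["subject_id"].iloc[0])
    return NwsStack(scan_id=scan_id, subject_id=subject_id, networks=networks)
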