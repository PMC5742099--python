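"""Synthetic test-retest cohorts of tractography tract tables.

Real studies of structural-network reliability rescan the same volunteers
several times and compare the networks within and between subjects.  This
module fabricates that design: each subject carries a latent connection
topology (distance-decaying baseline modulated by a subject-specific
modular structure plus subject-specific edge jitter), and each scan is a
noisy realization of the subject's latent tracts.  Output is one tract
table per (subject, scan) — the same substrate a tractography pipeline
would hand to the network builder — so the entire downstream stack can be
exercised without MRI data.

Nothing here simulates diffusion MRI physics or anatomy; the generator's
only goal is within-subject similarity, between-subject separation, and
realistic marginal scales for every per-tract quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: Fixed column order of the tract-table interchange format.
TRACT_COLUMNS = [
    "scan_id", "subject_id", "roi_i", "roi_j",
    "n_streamlines", "mean_length_mm", "wm_length_mm", "tract_volume_mm3",
    "mean_fa", "mean_md", "mean_rd",
]

# Approximate bounding box of an adult brain in mm (x: left-right,
# y: posterior-anterior, z: inferior-superior).
_BRAIN_BOX = np.array([[-70.0, 70.0], [-105.0, 72.0], [-45.0, 78.0]])


class InvalidParameterError(ValueError):
    pass


@dataclass
class RoiGeometry:
    """Parcellation geometry: region labels, centroids (mm), voxel counts."""

    roi_labels: list[str]
    centroids: np.ndarray          # (n, 3) mm
    voxel_counts: np.ndarray       # (n,) positive ints

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.voxel_counts = np.asarray(self.voxel_counts, dtype=int)
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise InvalidParameterError("duplicate ROI labels")
        if not np.all(np.isfinite(self.centroids)):
            raise InvalidParameterError("non-finite centroid")
        if np.any(self.voxel_counts < 1):
            raise InvalidParameterError("voxel counts must be >= 1")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


@dataclass
class CohortParams:
    """Knobs of the latent cohort model.

    Attributes
    ----------
    decay_mm
        Length scale of the exponential distance decay of connection
        probability and streamline count (mm).
    base_count
        Mean streamline count of a zero-distance connection; longer
        connections scale down by ``exp(-ED/decay_mm)``.
    connect_scale
        Multiplier on the distance-decayed connection probability;
        controls overall network density.
    n_modules
        Number of modules in each subject's planted partition.
    module_boost
        Multiplicative streamline-count boost for within-module pairs,
        applied as ``1 + module_boost``.
    between_subject_scale
        Standard deviation of the subject-specific log-normal jitter on
        per-edge mean counts — the fingerprint signal.
    scan_noise
        Scale of scan-level multiplicative (log-normal) fluctuation of
        per-tract means.  Counts are then drawn negative-binomially with
        fixed dispersion, so weak tracts are relatively much noisier
        than strong ones and can drop out of a scan entirely — the
        test-retest signature of streamline tractography.  Zero makes
        repeat scans identical (no sampling noise at all).
    nb_dispersion
        Negative-binomial size parameter r (variance = m + m^2/r) of the
        per-scan count draw.
    spurious_rate
        Expected number of scan-specific false-positive tracts, as a
        fraction of the subject's true tract count.  Spurious tracts are
        weak and traverse little white matter, so they are the prime
        target of both length thresholding and topological filtering.
    metric_noise
        Scan-level Gaussian noise s.d. on FA (and proportionally on
        MD/RD) around subject means.
    subject_geom_jitter_mm
        Per-subject centroid displacement emulating native-space anatomy
        (Euclidean distances differ across individuals).
    scan_geom_jitter_mm
        Per-scan residual centroid displacement (head position and
        registration error).  Zero when ``scan_noise`` is zero.
    """

    decay_mm: float = 40.0
    base_count: float = 80.0
    connect_scale: float = 1.8
    n_modules: int = 6
    module_boost: float = 1.0
    between_subject_scale: float = 0.6
    scan_noise: float = 0.15
    nb_dispersion: float = 100.0
    spurious_rate: float = 0.08
    metric_noise: float = 0.02
    subject_geom_jitter_mm: float = 2.5
    scan_geom_jitter_mm: float = 0.5

    def validate(self) -> None:
        for name in ("between_subject_scale", "scan_noise", "metric_noise",
                     "spurious_rate", "subject_geom_jitter_mm", "scan_geom_jitter_mm"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        if self.decay_mm <= 0 or self.base_count <= 0 or self.connect_scale <= 0 \
                or self.nb_dispersion <= 0:
            raise InvalidParameterError("decay_mm, base_count, connect_scale, nb_dispersion must be positive")
        if self.n_modules < 1:
            raise InvalidParameterError("n_modules must be >= 1")


#: Parameters of the low-noise regime: strong subject fingerprints,
#: small scan-to-scan variability.
LOW_NOISE = CohortParams(between_subject_scale=0.8, scan_noise=0.05, metric_noise=0.01)


@dataclass
class CohortManifest:
    """Bookkeeping for a generated cohort: who was scanned, with what seed."""

    subject_ids: list[str]
    scan_ids: dict[str, list[str]]
    n_rois: int
    seed: int
    params: CohortParams

    def pairs(self) -> list[tuple[str, str]]:
        return [(s, sc) for s in self.subject_ids for sc in self.scan_ids[s]]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d


def generate_roi_geometry(n_rois: int, seed: int) -> RoiGeometry:
    """Sample a parcellation: centroids in a brain-sized box, log-normal
    gray-matter voxel counts.

    Deterministic for a fixed seed.
    """
    if n_rois < 3:
        raise InvalidParameterError("need at least 3 ROIs")
    rng = np.random.default_rng(seed)
    lo, hi = _BRAIN_BOX[:, 0], _BRAIN_BOX[:, 1]
    centroids = rng.uniform(lo, hi, size=(n_rois, 3))
    # gray-matter ROI sizes are right-skewed; median a few hundred voxels
    voxel_counts = np.maximum(1, np.round(rng.lognormal(np.log(400.0), 0.5, size=n_rois))).astype(int)
    labels = [f"roi_{i + 1}" for i in range(n_rois)]
    return RoiGeometry(labels, centroids, voxel_counts)


def _euclidean(centroids: np.ndarray) -> np.ndarray:
    diff = centroids[:, None, :] - centroids[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _subject_latent(geometry: RoiGeometry, params: CohortParams, rng: np.random.Generator):
    """Draw one subject's latent edge set, mean counts and tract metrics."""
    n = geometry.n_rois
    ed = _euclidean(geometry.centroids)
    decay = np.exp(-ed / params.decay_mm)

    modules = rng.integers(0, params.n_modules, size=n)
    same_module = modules[:, None] == modules[None, :]
    boost = np.where(same_module, 1.0 + params.module_boost, 1.0)

    # subject fingerprint: per-edge log-normal jitter on mean counts
    z = rng.standard_normal((n, n))
    z = np.triu(z, 1)
    z = z + z.T
    jitter = np.exp(params.between_subject_scale * z)

    p_conn = np.clip(params.connect_scale * decay * boost, 0.0, 1.0)
    u = rng.random((n, n))
    u = np.triu(u, 1)
    u = u + u.T
    present = (u < p_conn) & ~np.eye(n, dtype=bool)

    mean_counts = params.base_count * decay * boost * jitter
    mean_counts = np.where(present, np.maximum(mean_counts, 1.0), 0.0)

    iu, ju = np.triu_indices(n, 1)
    mask = present[iu, ju]
    edges = np.stack([iu[mask], ju[mask]], axis=1)
    m = len(edges)

    lat = {
        "edges": edges,
        "mean_count": mean_counts[edges[:, 0], edges[:, 1]],
        # tracts curve, so mean streamline length exceeds the chord
        "mean_length": ed[edges[:, 0], edges[:, 1]] * rng.uniform(1.1, 1.6, m) + 2.0,
        "fa": np.clip(rng.normal(0.45, 0.12, m), 0.05, 0.95),
        "md": np.clip(rng.normal(8.0e-4, 0.8e-4, m), 1e-4, None),  # mm^2/s
    }
    # RD < MD by construction (RD averages the two smaller eigenvalues)
    lat["rd"] = lat["md"] * rng.uniform(0.55, 0.9, m)
    # white-matter offset: distance travelled through gray matter / CSF
    lat["wm_offset"] = rng.exponential(25.0, m)
    lat["volume"] = (1.0 + 0.05 * lat["mean_count"]) * lat["mean_length"] * rng.uniform(0.8, 1.2, m)
    # candidate ROI pairs for scan-specific false-positive tracts
    absent = ~present[iu, ju]
    lat["non_edges"] = np.stack([iu[absent], ju[absent]], axis=1)
    lat["non_edge_ed"] = ed[iu[absent], ju[absent]]
    return lat


def _scan_table(subject_id: str, scan_id: str, lat: dict, params: CohortParams,
                rng: np.random.Generator) -> pd.DataFrame:
    """Realize one scan of a subject's latent tracts as a tract table.

    Counts are negative-binomial with fixed dispersion around log-normally
    fluctuating per-scan means, so the relative noise grows as tracts get
    weaker; tracts whose draw is zero are absent from this scan, and a few
    spurious (false-positive) tracts are added.  With ``scan_noise == 0``
    every scan reproduces the latent table exactly.
    """
    m = len(lat["edges"])
    mu = lat["mean_count"]
    if params.scan_noise == 0:
        counts = np.maximum(1, np.round(mu)).astype(int)
        keep = np.ones(m, dtype=bool)
        length = lat["mean_length"].copy()
        volume = lat["volume"].copy()
    else:
        m_scan = mu * np.exp(rng.normal(0.0, params.scan_noise, m))
        r = params.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + m_scan), size=m)
        keep = counts >= 1  # weak tracts can vanish from a single scan
        length = lat["mean_length"] * np.exp(rng.normal(0.0, params.scan_noise / 2, m))
        volume = lat["volume"] * np.exp(rng.normal(0.0, params.scan_noise, m))
    if params.metric_noise == 0:
        fa, md, rd = lat["fa"].copy(), lat["md"].copy(), lat["rd"].copy()
    else:
        fa = np.clip(lat["fa"] + rng.normal(0.0, params.metric_noise, m), 0.0, 1.0)
        md = np.clip(lat["md"] * (1.0 + rng.normal(0.0, params.metric_noise, m)), 1e-5, None)
        rd = np.clip(lat["rd"] * (1.0 + rng.normal(0.0, params.metric_noise, m)), 1e-5, None)
    wm = np.maximum(length - lat["wm_offset"], 0.05)
    df = pd.DataFrame({
        "scan_id": scan_id,
        "subject_id": subject_id,
        "roi_i": lat["edges"][:, 0],
        "roi_j": lat["edges"][:, 1],
        "n_streamlines": counts,
        "mean_length_mm": length,
        "wm_length_mm": wm,
        "tract_volume_mm3": volume,
        "mean_fa": fa,
        "mean_md": md,
        "mean_rd": rd,
    }, columns=TRACT_COLUMNS)[keep]

    if params.scan_noise > 0 and params.spurious_rate > 0 and len(lat["non_edges"]):
        n_sp = min(rng.poisson(params.spurious_rate * m), len(lat["non_edges"]))
        if n_sp > 0:
            pick = rng.choice(len(lat["non_edges"]), size=n_sp, replace=False)
            sp_len = lat["non_edge_ed"][pick] * rng.uniform(1.1, 1.6, n_sp) + 2.0
            sp_md = np.clip(rng.normal(9.0e-4, 1.0e-4, n_sp), 1e-4, None)
            spurious = pd.DataFrame({
                "scan_id": scan_id,
                "subject_id": subject_id,
                "roi_i": lat["non_edges"][pick, 0],
                "roi_j": lat["non_edges"][pick, 1],
                "n_streamlines": 1 + rng.poisson(0.7, n_sp),
                "mean_length_mm": sp_len,
                # false positives barely traverse white matter, so the
                # 0-6 mm length sweep removes them first
                "wm_length_mm": rng.uniform(0.05, 6.0, n_sp),
                "tract_volume_mm3": sp_len * rng.uniform(0.5, 1.5, n_sp),
                "mean_fa": np.clip(rng.normal(0.25, 0.08, n_sp), 0.02, 0.6),
                "mean_md": sp_md,
                "mean_rd": sp_md * rng.uniform(0.7, 0.95, n_sp),
            }, columns=TRACT_COLUMNS)
            df = pd.concat([df, spurious], ignore_index=True)
    return df.reset_index(drop=True)


def generate_cohort(
    n_subjects: int,
    n_scans: int,
    geometry: RoiGeometry,
    params: CohortParams | None = None,
    seed: int = 0,
) -> tuple[CohortManifest, dict[tuple[str, str], pd.DataFrame], dict[tuple[str, str], RoiGeometry]]:
    """Generate a subjects x scans design of tract tables and geometries.

    Each subject gets a native-space geometry (template centroids plus a
    subject-specific displacement, so inter-centroid distances vary
    across individuals) and an independent latent network on it; each
    scan is a noisy draw around the subject's latent tracts, with its own
    residual geometry jitter.  Returns the manifest, tract tables and
    per-scan geometries, all keyed by ``(subject_id, scan_id)``.
    Deterministic for a fixed seed.
    """
    if n_subjects < 2 or n_scans < 2:
        raise InvalidParameterError("need at least 2 subjects and 2 scans")
    params = params or CohortParams()
    params.validate()

    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)
    subject_ids = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    scan_ids = {s: [f"scan-{j + 1:02d}" for j in range(n_scans)] for s in subject_ids}

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    geometries: dict[tuple[str, str], RoiGeometry] = {}
    for sid, sub_ss in zip(subject_ids, subject_seeds):
        streams = sub_ss.spawn(n_scans + 1)
        sub_rng = np.random.default_rng(streams[0])
        native = RoiGeometry(
            roi_labels=list(geometry.roi_labels),
            centroids=geometry.centroids
            + sub_rng.normal(0.0, params.subject_geom_jitter_mm, geometry.centroids.shape),
            voxel_counts=np.maximum(
                1, np.round(geometry.voxel_counts
                            * sub_rng.lognormal(0.0, 0.1, geometry.n_rois))).astype(int),
        )
        lat = _subject_latent(native, params, sub_rng)
        for scan, st in zip(scan_ids[sid], streams[1:]):
            rng = np.random.default_rng(st)
            if params.scan_noise > 0 and params.scan_geom_jitter_mm > 0:
                cent = native.centroids + rng.normal(
                    0.0, params.scan_geom_jitter_mm, native.centroids.shape)
            else:
                cent = native.centroids.copy()
            geometries[(sid, scan)] = RoiGeometry(list(native.roi_labels), cent,
                                                  native.voxel_counts.copy())
            tables[(sid, scan)] = _scan_table(sid, scan, lat, params, rng)

    manifest = CohortManifest(subject_ids, scan_ids, geometry.n_rois, seed, params)
    return manifest, tables, geometries
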