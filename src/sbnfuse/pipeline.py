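"""End-to-end orchestration over a subjects x scans cohort.

The canonical flow, per scan: tract table -> nine weighted networks ->
pairwise diffusion dissimilarity -> fusion weights -> integrated network
-> OMST filtering.  Across scans: scan-by-scan diffusion distance
matrices for the integrated and filtered networks (and optionally each
weighting strategy), k-NN subject recognition, QCI, metric tables and
their ICCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import MetricTable, ScanDistanceMatrix, icc, knn_recognition, qci
from .gddm import GddmOptions, gddm_distance
from .integration import integrate_scan
from .metrics import NETWORK_METRICS, compute_metrics
from .network import WeightedNetwork
from .nws import NWS_NAMES, build_nws
from .omst import omst_filter
from .synthetic import CohortManifest, CohortParams, generate_cohort, generate_roi_geometry


@dataclass
class PipelineConfig:
    """Everything needed to re-run the full analysis."""

    n_subjects: int = 5
    n_scans: int = 5
    n_rois: int = 90
    length_threshold_mm: float = 0.0
    gddm: GddmOptions = field(default_factory=GddmOptions)
    prescale_mode: str = "max"
    omst_max_rounds: int | None = None
    icc_form: str = "1_1"
    knn_k: int = 4
    seed: int = 0
    params: CohortParams = field(default_factory=CohortParams)


@dataclass
class ScanResult:
    subject_id: str
    scan_id: str
    stack: object
    fused: WeightedNetwork        # integrated network
    filtered: WeightedNetwork     # after OMST
    weights: np.ndarray           # the nine fusion weights
    omst_rounds: int


@dataclass
class PipelineResult:
    manifest: CohortManifest
    scans: list[ScanResult]
    distance_fused: ScanDistanceMatrix
    distance_filtered: ScanDistanceMatrix
    recognition: dict
    qci_fused: float
    qci_filtered: float
    metric_tables: dict[tuple[str, str], MetricTable]
    icc_table: pd.DataFrame


def scan_distance_matrix(networks: list[WeightedNetwork],
                         subject_labels: list[str], scan_labels: list[str],
                         options: GddmOptions | None = None) -> ScanDistanceMatrix:
    """Pairwise diffusion distances between all scans' networks."""
    m = len(networks)
    D = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            d, _ = gddm_distance(networks[a], networks[b], options)
            D[a, b] = D[b, a] = d
    return ScanDistanceMatrix(D, list(subject_labels), list(scan_labels))


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Simulate a cohort and run the complete method stack on it."""
    config = config or PipelineConfig()
    geometry = generate_roi_geometry(config.n_rois, config.seed)
    manifest, tables, geometries = generate_cohort(config.n_subjects, config.n_scans,
                                                   geometry, config.params, config.seed)

    scans: list[ScanResult] = []
    for (sid, scan), table in tables.items():
        stack = build_nws(table, geometries[(sid, scan)], config.length_threshold_mm,
                          scan_id=scan, subject_id=sid)
        fused, w, _ = integrate_scan(stack, prescale_mode=config.prescale_mode,
                                     gddm_options=config.gddm)
        res = omst_filter(fused, max_rounds=config.omst_max_rounds)
        scans.append(ScanResult(sid, scan, stack, fused, res.filtered, w, res.n_rounds))

    subject_labels = [s.subject_id for s in scans]
    scan_labels = [s.scan_id for s in scans]
    d_fused = scan_distance_matrix([s.fused for s in scans], subject_labels,
                                   scan_labels, config.gddm)
    d_filt = scan_distance_matrix([s.filtered for s in scans], subject_labels,
                                  scan_labels, config.gddm)

    acc, preds = knn_recognition(d_filt, k=config.knn_k)
    recognition = {"k": config.knn_k, "accuracy": acc, "predicted": preds,
                   "true": subject_labels}

    # metric tables + ICC for the fused and filtered variants
    metric_tables: dict[tuple[str, str], MetricTable] = {}
    icc_rows = []
    subj_ids = manifest.subject_ids
    scan_ids = manifest.scan_ids[subj_ids[0]]
    for variant, getter in (("fused", lambda s: s.fused), ("filtered", lambda s: s.filtered)):
        records = {(s.subject_id, s.scan_id):
                   compute_metrics(getter(s), s.scan_id, s.subject_id, variant)
                   for s in scans}
        for metric in NETWORK_METRICS:
            grid = np.array([[records[(su, sc)].network_level[metric]
                              for sc in scan_ids] for su in subj_ids])
            mt = MetricTable(grid, metric=metric, variant=variant)
            metric_tables[(variant, metric)] = mt
            try:
                val = icc(mt, form=config.icc_form)
            except ValueError:
                val = np.nan
            icc_rows.append({"variant": variant, "metric": metric, "icc": val})

    return PipelineResult(
        manifest=manifest, scans=scans,
        distance_fused=d_fused, distance_filtered=d_filt,
        recognition=recognition,
        qci_fused=qci(d_fused), qci_filtered=qci(d_filt),
        metric_tables=metric_tables,
        icc_table=pd.DataFrame(icc_rows),
    )
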