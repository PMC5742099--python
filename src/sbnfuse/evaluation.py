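"""Reliability and discriminability statistics for test-retest designs.

Reliability of a scalar network metric over a subjects x scans grid is
quantified with intraclass correlation coefficients (Shrout & Fleiss
forms 1,1 / 2,1 / 3,1), and distributions are compared with the Wilcoxon
rank-sum test.  Discriminability of whole networks uses the diffusion
distance between all scan pairs: leave-one-out k-NN subject recognition,
a quality-of-clustering index (QCI) contrasting equalized between-subject
with within-subject distances, and classical MDS embeddings for
visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .network import validate_weights
from .synthetic import InvalidParameterError

ICC_FORMS = ("1_1", "2_1", "3_1")


class DegenerateVarianceError(ValueError):
    """All table values identical: ICC is undefined (0/0)."""


@dataclass
class MetricTable:
    """Subjects x scans grid of one scalar metric."""

    values: np.ndarray          # (n_subjects, n_scans)
    metric: str = ""
    variant: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise InvalidParameterError("need a complete grid with >= 2 subjects and >= 2 scans")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("metric table has missing/non-finite cells")


def icc(table: MetricTable | np.ndarray, form: str = "1_1") -> float:
    """Intraclass correlation coefficient of a subjects x scans grid.

    Forms (single-rater):

    * ``1_1`` one-way random:      (MSB - MSW) / (MSB + (k-1) MSW)
    * ``2_1`` two-way random:      (MSB - MSE) / (MSB + (k-1) MSE + k (MSC - MSE)/n)
    * ``3_1`` two-way mixed:       (MSB - MSE) / (MSB + (k-1) MSE)

    where MSB/MSW are the between/within-subject mean squares and MSC/MSE
    the session and residual mean squares of the two-way layout.
    """
    x = table.values if isinstance(table, MetricTable) else np.asarray(table, dtype=float)
    if form not in ICC_FORMS:
        raise InvalidParameterError(f"form must be one of {ICC_FORMS}")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateVarianceError("all values identical; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_between = k * ((row_means - grand) ** 2).sum()
    ss_within = ((x - row_means[:, None]) ** 2).sum()
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))

    if form == "1_1":
        return float((msb - msw) / (msb + (k - 1) * msw))

    ss_col = n * ((col_means - grand) ** 2).sum()
    ss_err = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msc = ss_col / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if mse == 0 and msb == 0:
        raise DegenerateVarianceError("degenerate two-way layout")
    if form == "3_1":
        return float((msb - mse) / (msb + (k - 1) * mse))
    return float((msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n))


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when the combined sample has at most 12 values,
    normal approximation (tie-corrected) otherwise.  Returns
    ``(rank-sum statistic of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be nonempty")
    method = "exact" if (x.size + y.size <= 12 and
                         len(np.unique(np.concatenate([x, y]))) == x.size + y.size) else "asymptotic"
    u, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
    if u == x.size * y.size / 2:  # perfectly balanced ranks (e.g. identical samples)
        p = 1.0
    # rank-sum statistic W = U + n_x (n_x + 1) / 2
    w = float(u + x.size * (x.size + 1) / 2)
    return w, float(p)


@dataclass
class ScanDistanceMatrix:
    """Diffusion distances between every pair of scans in a cohort."""

    D: np.ndarray
    subject_labels: list[str]
    scan_labels: list[str]

    def __post_init__(self) -> None:
        self.D = validate_weights(self.D)
        m = self.D.shape[0]
        if len(self.subject_labels) != m or len(self.scan_labels) != m:
            raise InvalidParameterError("labels must match matrix size")


def knn_recognition(D: ScanDistanceMatrix, k: int = 4) -> tuple[float, list[str]]:
    """Leave-one-out k-NN subject recognition from scan distances.

    Each scan is assigned the majority subject label among its k nearest
    other scans; ties break by smaller summed distance, then by subject
    order of first appearance.  Returns (accuracy, predicted labels).
    """
    m = D.D.shape[0]
    if k <= 0:
        raise InvalidParameterError("k must be positive")
    if k >= m:
        raise InvalidParameterError("k must be smaller than the number of other scans")
    subj_order = list(dict.fromkeys(D.subject_labels))
    preds: list[str] = []
    hits = 0
    for row in range(m):
        d = D.D[row].copy()
        d[row] = np.inf
        # stable nearest-k: sort by (distance, index)
        nn = np.lexsort((np.arange(m), d))[:k]
        votes: dict[str, tuple[int, float]] = {}
        for idx in nn:
            s = D.subject_labels[idx]
            c, tot = votes.get(s, (0, 0.0))
            votes[s] = (c + 1, tot + d[idx])
        best = min(votes.items(),
                   key=lambda kv: (-kv[1][0], kv[1][1], subj_order.index(kv[0])))
        preds.append(best[0])
        hits += best[0] == D.subject_labels[row]
    return hits / m, preds


def qci(D: ScanDistanceMatrix) -> float:
    """Quality-of-clustering index of a subjects x scans distance matrix.

    Ratio of the mean summed between-subject distance (over all subject
    pairs and all scan combinations) to the mean summed within-subject
    distance, equalized by scans(scans-1)/2 / scans^2 so a constant
    matrix scores exactly 1.  Values above 1 indicate subject
    separability; the index is invariant to rescaling of D.
    """
    subjects = list(dict.fromkeys(D.subject_labels))
    rows = {s: np.flatnonzero(np.asarray(D.subject_labels) == s) for s in subjects}
    n_scans = {s: len(r) for s, r in rows.items()}
    if len(subjects) < 2 or min(n_scans.values()) < 2:
        raise InvalidParameterError("need >= 2 subjects with >= 2 scans each")
    if len(set(n_scans.values())) != 1:
        raise InvalidParameterError("design must be complete (equal scans per subject)")
    scans = n_scans[subjects[0]]

    between = 0.0
    for a in range(len(subjects)):
        for b in range(a + 1, len(subjects)):
            between += D.D[np.ix_(rows[subjects[a]], rows[subjects[b]])].sum()
    n_pairs = len(subjects) * (len(subjects) - 1) / 2
    numerator = between / n_pairs

    within = 0.0
    for s in subjects:
        blk = D.D[np.ix_(rows[s], rows[s])]
        within += np.triu(blk, 1).sum()
    denominator = within / len(subjects)
    if denominator == 0:
        raise ZeroDivisionError("within-subject distances are all zero; QCI undefined")

    prefactor = (scans * (scans - 1) / 2) / (scans * scans)
    return float(prefactor * numerator / denominator)


def mds_embed(D: np.ndarray | ScanDistanceMatrix, dims: int = 3) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centers the squared distances and keeps the top ``dims``
    nonnegative eigenpairs.  Exactly recovers Euclidean-realizable
    configurations (up to rigid motion) when ``dims`` is large enough.
    """
    d = D.D if isinstance(D, ScanDistanceMatrix) else validate_weights(np.asarray(D, dtype=float))
    m = d.shape[0]
    if dims >= m:
        raise InvalidParameterError("dims must be smaller than the number of points")
    j = np.eye(m) - np.full((m, m), 1.0 / m)
    b = -0.5 * j @ (d ** 2) @ j
    lam, v = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1][:dims]
    lam_top = np.clip(lam[order], 0.0, None)
    return v[:, order] * np.sqrt(lam_top)
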