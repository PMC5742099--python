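"""ICC, rank-sum, k-NN recognition, QCI and MDS: oracles and properties."""

import numpy as np
import pytest

from sbnfuse import (
    MetricTable,
    ScanDistanceMatrix,
    icc,
    knn_recognition,
    mds_embed,
    qci,
    wilcoxon_ranksum,
)
from sbnfuse.evaluation import DegenerateVarianceError
from sbnfuse.synthetic import InvalidParameterError


def _anova_icc_oracle(x: np.ndarray) -> float:
    """ICC(1,1) from raw one-way ANOVA sums of squares (independent coding)."""
    n, k = x.shape
    grand = x.sum() / x.size
    ss_total = ((x - grand) ** 2).sum()
    ss_within = sum(((x[i] - x[i].mean()) ** 2).sum() for i in range(n))
    ss_between = ss_total - ss_within
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestIcc:
    def test_perfect_agreement(self):
        assert icc(np.array([[1.0, 1.0], [3.0, 3.0]])) == pytest.approx(1.0)

    def test_pure_disagreement(self):
        # MSB = 0, MSW = 2 -> (0-2)/(0+2) = -1
        assert icc(np.array([[1.0, 3.0], [3.0, 1.0]])) == pytest.approx(-1.0)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(6, 4))
        assert icc(x) == pytest.approx(_anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(22)
        x = rng.normal(size=(8, 3))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "y": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
        ref = ref.set_index("Type")["ICC"]
        for form, name in (("1_1", "ICC(1,1)"), ("2_1", "ICC(A,1)"), ("3_1", "ICC(C,1)")):
            assert icc(x, form=form) == pytest.approx(float(ref[name]), abs=1e-8)

    def test_degenerate_table(self):
        with pytest.raises(DegenerateVarianceError):
            icc(np.ones((3, 3)))

    def test_parameter_recovery(self):
        """One-way random-effects simulation recovers the true ICC."""
        rng = np.random.default_rng(23)
        for rho in (0.2, 0.5, 0.9):
            estimates = []
            for _ in range(200):
                subj = rng.normal(0, np.sqrt(rho), size=(50, 1))
                x = subj + rng.normal(0, np.sqrt(1 - rho), size=(50, 5))
                estimates.append(icc(x))
            assert abs(np.mean(estimates) - rho) <= 0.07


class TestWilcoxonRanksum:
    def test_exact_small_sample(self):
        # {1,2,3} vs {4,5,6}: most extreme of C(6,3)=20 splits -> p = 2/20
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(24)
        x = rng.normal(0, 1, 40)
        ps = [wilcoxon_ranksum(x, x + shift)[1] for shift in (0.2, 0.8, 2.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_sample(self):
        with pytest.raises(InvalidParameterError):
            wilcoxon_ranksum([], [1.0])


def _block_design(n_subjects=5, n_scans=5, within=0.0, between=1.0):
    m = n_subjects * n_scans
    subjects = [f"s{i}" for i in range(n_subjects) for _ in range(n_scans)]
    scans = [f"r{j}" for _ in range(n_subjects) for j in range(n_scans)]
    D = np.full((m, m), between)
    for i in range(n_subjects):
        D[i * n_scans:(i + 1) * n_scans, i * n_scans:(i + 1) * n_scans] = within
    np.fill_diagonal(D, 0.0)
    return ScanDistanceMatrix(D, subjects, scans)


class TestKnnRecognition:
    def test_perfect_block_structure(self):
        acc, preds = knn_recognition(_block_design(), k=4)
        assert acc == 1.0
        assert preds == _block_design().subject_labels

    def test_random_distance_null(self):
        """Uninformative distances give chance accuracy.

        For LOOCV with k=1 the nearest scan is uniform over the m-1 others,
        of which scans-1 share the subject, so the exact chance level is
        (scans-1)/(m-1) = 4/24; k=4 must also stay near chance.
        """
        rng = np.random.default_rng(25)
        base = _block_design()
        acc1, acc4 = [], []
        for _ in range(200):
            d = rng.uniform(0.1, 1.0, (25, 25))
            d = np.triu(d, 1)
            D = ScanDistanceMatrix(d + d.T, base.subject_labels, base.scan_labels)
            acc1.append(knn_recognition(D, k=1)[0])
            acc4.append(knn_recognition(D, k=4)[0])
        assert np.mean(acc1) == pytest.approx(4 / 24, abs=0.02)
        assert np.mean(acc4) < 0.25

    def test_k1_nearest_same_subject(self):
        acc, _ = knn_recognition(_block_design(within=0.1), k=1)
        assert acc == 1.0

    def test_invalid_k(self):
        with pytest.raises(InvalidParameterError):
            knn_recognition(_block_design(), k=0)


class TestQci:
    def test_constant_matrix_scores_one(self):
        D = _block_design(within=2.0, between=2.0)
        assert qci(D) == pytest.approx(1.0)

    def test_two_by_two_hand_computation(self):
        # 2 subjects x 2 scans, within = 1, between = 2:
        # prefactor 1/4; numerator 2*4 = 8 over 1 pair; denominator 1 -> QCI 2
        D = _block_design(n_subjects=2, n_scans=2, within=1.0, between=2.0)
        assert qci(D) == pytest.approx(2.0)

    def test_scale_invariance(self):
        D = _block_design(within=0.5, between=1.7)
        ref = qci(D)
        scaled = ScanDistanceMatrix(7.3 * D.D, D.subject_labels, D.scan_labels)
        assert qci(scaled) == pytest.approx(ref, abs=1e-12)

    def test_monotone_in_between_subject_distance(self):
        vals = [qci(_block_design(within=0.5, between=b)) for b in (1.0, 2.0, 4.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_zero_within_raises(self):
        with pytest.raises(ZeroDivisionError):
            qci(_block_design(within=0.0))


class TestMdsEmbed:
    def test_equilateral_triangle(self):
        D = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        x = mds_embed(D, dims=2)
        recon = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        np.testing.assert_allclose(recon, D, atol=1e-8)

    def test_duplicate_points_coincide(self):
        D = np.array([[0.0, 0, 2], [0, 0, 2], [2, 2, 0]])
        x = mds_embed(D, dims=1)
        np.testing.assert_allclose(x[0], x[1], atol=1e-9)

    def test_exact_recovery_of_euclidean_distances(self):
        rng = np.random.default_rng(26)
        pts = rng.normal(size=(10, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        x = mds_embed(D, dims=9)
        recon = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        np.testing.assert_allclose(recon, D, atol=1e-8)

    def test_matches_scikit_bio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(27)
        pts = rng.normal(size=(8, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = mds_embed(D, dims=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D), number_of_dimensions=3)
        theirs = ref.samples.to_numpy()
        # same configuration up to per-axis sign
        for axis in range(3):
            assert (np.allclose(ours[:, axis], theirs[:, axis], atol=1e-6)
                    or np.allclose(ours[:, axis], -theirs[:, axis], atol=1e-6))

    def test_dims_too_large(self):
        with pytest.raises(InvalidParameterError):
            mds_embed(np.zeros((3, 3)), dims=3)
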