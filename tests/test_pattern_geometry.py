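"""Coactivity patterns, PCA dimensionality and subspace geometry."""

import numpy as np
import pytest

from tectodyn.pattern_geometry import (
    CoactivitySeries,
    PatternSet,
    balanced_projection_analysis,
    build_subspace,
    coactivity_threshold,
    epoch_cosine_similarity,
    mean_coactivity,
    pca_dimensionality,
    select_patterns,
    unexplained_fraction,
)
from tectodyn.preprocessing import BinaryRaster, EpochLabels


def _raster(B):
    B = np.asarray(B, dtype=np.uint8)
    return BinaryRaster(B=B, thresholds=np.zeros(B.shape[0]))


def _labels(label_list, sa_end=None):
    arr = np.asarray(label_list, dtype="<U4")
    sa_end = sa_end if sa_end is not None else int((arr == "SA").sum())
    return EpochLabels(labels=arr, stimulus_position=np.full(len(arr), np.nan),
                       sa_end_frame=sa_end)


class TestCoactivityThreshold:
    def test_all_ones_raster_admits_nothing(self):
        raster = _raster(np.ones((5, 60)))
        series = coactivity_threshold(raster, n_shuffles=50, seed=0)
        assert series.threshold == 6  # above the only attainable count
        assert len(series.significant_frames()) == 0

    def test_all_zero_raster(self):
        series = coactivity_threshold(_raster(np.zeros((5, 60))), n_shuffles=50, seed=0)
        assert series.threshold == 1
        assert len(series.significant_frames()) == 0

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(1)
        B = (rng.random((5, 200)) < 0.3).astype(np.uint8)
        series = coactivity_threshold(_raster(B), n_shuffles=100, alpha=0.05, seed=7)

        # brute-force re-implementation with the same surrogate stream
        oracle_rng = np.random.default_rng(7)
        all_counts = []
        for _ in range(100):
            surr = oracle_rng.permuted(B, axis=1)
            for t in range(200):
                all_counts.append(int(surr[:, t].sum()))
        thr = None
        for c in range(0, 7):
            frac = sum(1 for x in all_counts if x >= c) / len(all_counts)
            if frac < 0.05:
                thr = max(c, 1)
                break
        assert series.threshold == thr
        assert series.counts.tolist() == B.sum(axis=0).tolist()

    def test_row_shuffle_preserves_per_neuron_counts(self):
        rng = np.random.default_rng(2)
        B = (rng.random((8, 100)) < 0.2).astype(np.uint8)
        surr = np.random.default_rng(3).permuted(B, axis=1)
        assert surr.sum(axis=1).tolist() == B.sum(axis=1).tolist()

    def test_per_surrogate_max_method_available(self):
        rng = np.random.default_rng(4)
        B = (rng.random((6, 150)) < 0.25).astype(np.uint8)
        pooled = coactivity_threshold(_raster(B), n_shuffles=100, seed=0)
        permax = coactivity_threshold(_raster(B), n_shuffles=100, seed=0,
                                      method="per_surrogate_max")
        assert permax.threshold >= pooled.threshold  # stricter null statistic


class TestSelectPatterns:
    def test_single_peak_selected(self):
        B = np.zeros((4, 3), dtype=np.uint8)
        B[:1, 0] = 1
        B[:3, 1] = 1
        B[:1, 2] = 1
        series = CoactivitySeries(counts=np.array([1, 3, 1]), threshold=2)
        sets = select_patterns(series, _raster(B), _labels(["SA"] * 3))
        assert sets["SA"].frames.tolist() == [1]
        assert sets["SA"].patterns[0].tolist() == B[:, 1].tolist()

    def test_plateau_takes_first_frame(self):
        series = CoactivitySeries(counts=np.array([1, 3, 3, 1]), threshold=2)
        B = np.zeros((4, 4), dtype=np.uint8)
        B[:3, 1] = B[:3, 2] = 1
        sets = select_patterns(series, _raster(B), _labels(["SA"] * 4))
        assert sets["SA"].frames.tolist() == [1]

    def test_matches_naive_peak_scan_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 8, size=120)
        B = np.zeros((8, 120), dtype=np.uint8)
        for t, c in enumerate(counts):
            B[:c, t] = 1
        series = CoactivitySeries(counts=counts, threshold=4)
        sets = select_patterns(series, _raster(B), _labels(["SA"] * 120))

        peaks = []
        t = 0
        while t < len(counts):
            j = t
            while j + 1 < len(counts) and counts[j + 1] == counts[t]:
                j += 1
            left = counts[t - 1] if t > 0 else -np.inf
            right = counts[j + 1] if j + 1 < len(counts) else -np.inf
            if counts[t] > left and counts[t] > right and counts[t] >= 4:
                peaks.append(t)
            t = j + 1
        assert sets["SA"].frames.tolist() == peaks

    def test_unlabelled_frames_discarded(self):
        series = CoactivitySeries(counts=np.array([1, 5, 1, 5, 1]), threshold=2)
        B = np.zeros((6, 5), dtype=np.uint8)
        B[:5, 1] = B[:5, 3] = 1
        labels = _labels(["SA", "SA", "SA", "none", "none"], sa_end=3)
        sets = select_patterns(series, _raster(B), labels)
        assert sets["SA"].frames.tolist() == [1]
        assert all(len(sets[e]) == 0 for e in ("EA", "SE"))


class TestMeanCoactivity:
    def test_single_and_multiple_peaks(self):
        counts = np.array([1, 7, 1, 4, 1, 6, 1])
        series = CoactivitySeries(counts=counts, threshold=3)
        B = np.zeros((8, 7), dtype=np.uint8)
        for t, c in enumerate(counts):
            B[:c, t] = 1
        sets = select_patterns(series, _raster(B),
                               _labels(["SA"] * 3 + ["EA"] * 4, sa_end=3))
        means = mean_coactivity(series, sets)
        assert means["SA"] == pytest.approx(7.0)
        assert means["EA"] == pytest.approx(5.0)  # peaks {4, 6}


class TestPcaDimensionality:
    def test_rank_one_data(self):
        rng = np.random.default_rng(6)
        u = rng.normal(size=(10, 1))
        v = rng.normal(size=(1, 50))
        assert pca_dimensionality(u @ v, np.arange(50)) == 1

    def test_constructed_spectrum_5_3_1_1(self):
        """Sample variances {5,3,1,1}: two components reach 80%."""
        rng = np.random.default_rng(7)
        t, n = 40, 6
        q, _ = np.linalg.qr(np.column_stack([np.ones(t), rng.normal(size=(t, 4))]))
        v = q[:, 1:]  # orthonormal, each orthogonal to the mean direction
        load = np.diag(np.sqrt(np.array([5.0, 3.0, 1.0, 1.0]) * t))
        basis, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        X = basis @ load @ v.T
        assert pca_dimensionality(X, np.arange(t)) == 2

    def test_dimension_bounded_by_rank(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 5))
        k = pca_dimensionality(X, np.arange(5))
        assert k <= min(5 - 1, 12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca_dimensionality(np.ones((4, 10)), np.arange(10))


class TestCosineSimilarity:
    def _ps(self, patterns, epoch="SA"):
        return PatternSet(epoch=epoch, patterns=np.asarray(patterns, dtype=float),
                          frames=np.arange(len(patterns)))

    def test_identical_singletons(self):
        p = self._ps([[1, 1, 0]])
        q = self._ps([[1, 1, 0]], epoch="EA")
        assert epoch_cosine_similarity(p, q) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        p = self._ps([[1, 1, 0, 0]])
        q = self._ps([[0, 0, 1, 1]], epoch="EA")
        assert epoch_cosine_similarity(p, q) == pytest.approx(0.0)

    def test_half_shared_support(self):
        p = self._ps([[1, 1, 0]])
        q = self._ps([[1, 0, 1]], epoch="EA")
        assert epoch_cosine_similarity(p, q) == pytest.approx(0.5)

    def test_zero_pattern_excluded_with_warning(self):
        p = self._ps([[1, 0], [0, 0]])
        q = self._ps([[1, 0]], epoch="EA")
        with pytest.warns(UserWarning):
            v = epoch_cosine_similarity(p, q)
        assert v == pytest.approx(1.0)


class TestSubspace:
    def test_standard_basis_patterns(self):
        sub = build_subspace(np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float))
        assert sub.dim == 2
        assert np.allclose(sub.projector, np.diag([1.0, 1.0, 0.0, 0.0]))

    def test_duplicated_pattern_rank_one(self):
        p = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert build_subspace(p).dim == 1

    def test_projector_idempotent_and_symmetric(self):
        rng = np.random.default_rng(9)
        sub = build_subspace(rng.normal(size=(5, 12)))
        P = sub.projector
        assert np.allclose(P, P.T, atol=1e-10)
        assert np.linalg.norm(P @ P - P) <= 1e-8
        assert np.allclose(sub.U.T @ sub.U, np.eye(sub.dim), atol=1e-10)

    def test_all_zero_patterns_rejected(self):
        with pytest.raises(ValueError):
            build_subspace(np.zeros((3, 4)))


class TestUnexplainedFraction:
    def test_analytic_cases(self):
        sub = build_subspace(np.array([[1, 0, 0], [0, 1, 0]], dtype=float))
        assert unexplained_fraction(np.array([0.3, -0.2, 0.0]), sub) == pytest.approx(0.0, abs=1e-12)
        assert unexplained_fraction(np.array([0.0, 0.0, 2.0]), sub) == pytest.approx(1.0)
        p = np.ones(3) / np.sqrt(3)
        assert unexplained_fraction(p, sub) == pytest.approx(1 / np.sqrt(3))

    def test_pythagoras_identity(self):
        rng = np.random.default_rng(10)
        sub = build_subspace(rng.normal(size=(6, 20)))
        for _ in range(100):
            p = rng.normal(size=20)
            proj = sub.project(p)
            resid = p - proj
            assert abs(np.dot(proj, resid)) < 1e-10
            assert (np.linalg.norm(proj) ** 2 + np.linalg.norm(resid) ** 2
                    == pytest.approx(np.linalg.norm(p) ** 2, rel=1e-10))

    def test_zero_pattern_rejected(self):
        sub = build_subspace(np.eye(3))
        with pytest.raises(ValueError):
            unexplained_fraction(np.zeros(3), sub)


class TestBalancedProjection:
    def _sets(self, pools):
        return {
            e: PatternSet(epoch=e, patterns=p, frames=np.arange(len(p)))
            for e, p in pools.items()
        }

    def test_shared_subspace_gives_zero_fractions(self):
        rng = np.random.default_rng(11)
        basis, _ = np.linalg.qr(rng.normal(size=(15, 3)))
        pools = {
            e: (rng.normal(size=(10, 3)) @ basis.T)
            for e in ("EA", "SA", "SE")
        }
        pairs, summary = balanced_projection_analysis(
            self._sets(pools), n_select=4, n_repeats=20, seed=0
        )
        assert (pairs["mean_unexplained"] < 1e-8).all()
        assert all(v < 1e-8 for v in summary.values())

    def test_analytic_orthogonal_component(self):
        """EA = SA-plane patterns plus beta x orthogonal unit -> beta/sqrt(1+beta^2)."""
        rng = np.random.default_rng(12)
        n = 12
        basis, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        plane, q = basis[:, :3], basis[:, 3]
        beta = 0.75

        sa = rng.normal(size=(10, 3)) @ plane.T
        se = rng.normal(size=(10, 3)) @ plane.T
        norms = np.linalg.norm(sa, axis=1)
        ea = sa + beta * norms[:, None] * q[None, :]
        pairs, _ = balanced_projection_analysis(
            self._sets({"EA": ea, "SA": sa, "SE": se}),
            n_select=5, n_repeats=10, seed=1,
        )
        got = pairs.loc[
            (pairs.target_epoch == "EA") & (pairs.subspace_epoch == "SA"),
            "mean_unexplained",
        ].iloc[0]
        assert got == pytest.approx(beta / np.sqrt(1 + beta ** 2), rel=1e-6)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(13)
        pools = {e: rng.normal(size=(12, 8)) for e in ("EA", "SA", "SE")}
        a = balanced_projection_analysis(self._sets(pools), n_select=5,
                                         n_repeats=15, seed=3)
        b = balanced_projection_analysis(self._sets(pools), n_select=5,
                                         n_repeats=15, seed=3)
        assert a[0]["mean_unexplained"].tolist() == b[0]["mean_unexplained"].tolist()

    def test_oversized_selection_rejected(self):
        rng = np.random.default_rng(14)
        pools = {e: rng.normal(size=(6, 5)) for e in ("EA", "SA", "SE")}
        with pytest.raises(ValueError, match="n_select"):
            balanced_projection_analysis(self._sets(pools), n_select=9, seed=0)

    def test_larger_selection_does_not_increase_unexplained(self):
        rng = np.random.default_rng(15)
        pools = {e: rng.normal(size=(20, 10)) for e in ("EA", "SA", "SE")}
        sets = self._sets(pools)
        small = balanced_projection_analysis(sets, n_select=4, n_repeats=40, seed=2)
        large = balanced_projection_analysis(sets, n_select=8, n_repeats=40, seed=2)
        assert (large[1]["1 - P_SA"] <= small[1]["1 - P_SA"] + 1e-9)
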