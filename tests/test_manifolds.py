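"""Result-manifold geometry: grouping, mean-field capacity against the
LP-separability oracle, and invariances."""

import numpy as np
import pytest

from numtwin.manifolds import (CoverageError, DegenerateGeometryError,
                               EmpiricalCapacity, ManifoldSet,
                               center_correlation, empirical_capacity,
                               group_by_result, linearly_separable,
                               mft_manifold_metrics)
from numtwin.stimuli import ADD, SUB, ProblemSpec


def point_manifolds(n_points, dim, rng, scale=1.0):
    centers = rng.normal(size=(n_points, dim)) * scale
    return ManifoldSet(points=[c[None, :] for c in centers],
                       labels=list(range(n_points)))


class TestGrouping:
    def test_default_task_gives_19_by_20(self, problems, rng):
        acts = rng.random((380, 6))
        ms = group_by_result(acts, problems)
        assert ms.n_manifolds == 19
        assert all(p.shape[0] == 20 for p in ms.points)

    def test_problems_sharing_result_share_manifold(self, rng):
        specs = [ProblemSpec(2, 7, ADD), ProblemSpec(5, 4, ADD),
                 ProblemSpec(9, 0, SUB)]
        acts = rng.random((3, 4))
        ms = group_by_result(acts, specs, expected_results=[9])
        assert ms.n_manifolds == 1 and ms.points[0].shape[0] == 3

    def test_missing_result_raises(self, rng):
        specs = [ProblemSpec(1, 1, ADD)]
        with pytest.raises(CoverageError):
            group_by_result(rng.random((1, 4)), specs,
                            expected_results=range(19))


class TestMeanFieldMetrics:
    def test_point_manifolds_reach_cover_limit(self, rng):
        """Zero-radius manifolds with independent Gaussian centers in high
        ambient dimension have capacity 2 (function-counting limit)."""
        ms = point_manifolds(16, 100, rng)
        m = mft_manifold_metrics(ms, n_samples=400, rng=1)
        assert m.capacity == pytest.approx(2.0, rel=0.1)
        assert m.radius == pytest.approx(0.0, abs=1e-9)

    def test_dimension_bounded_by_subspace(self, rng):
        # points confined to a 3-dimensional subspace of a 40-dim space
        basis = rng.normal(size=(3, 40))
        pts = [rng.normal(size=(8, 3)) @ basis + rng.normal(size=40) * 3
               for _ in range(5)]
        ms = ManifoldSet(points=pts, labels=list(range(5)))
        m = mft_manifold_metrics(ms, n_samples=150, rng=0)
        assert m.dimension <= 3.0 + 1e-6

    def test_rotation_and_scale_invariance(self, rng):
        pts = [rng.normal(size=(6, 12)) + rng.normal(size=12) * 2
               for _ in range(4)]
        ms = ManifoldSet(points=pts, labels=list(range(4)))
        q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        ms_rot = ManifoldSet(points=[3.7 * p @ q for p in pts],
                             labels=list(range(4)))
        a = mft_manifold_metrics(ms, n_samples=250, rng=5)
        b = mft_manifold_metrics(ms_rot, n_samples=250, rng=5)
        assert b.capacity == pytest.approx(a.capacity, rel=1e-6)
        assert b.dimension == pytest.approx(a.dimension, rel=1e-6)
        assert b.radius == pytest.approx(a.radius, rel=1e-6)

    def test_degenerate_points_rejected(self):
        pts = [np.ones((3, 5)), np.ones((3, 5))]
        with pytest.raises(DegenerateGeometryError):
            mft_manifold_metrics(ManifoldSet(points=pts, labels=[0, 1]))

    def test_seed_determinism(self, rng):
        ms = point_manifolds(8, 30, rng)
        a = mft_manifold_metrics(ms, n_samples=100, rng=3)
        b = mft_manifold_metrics(ms, n_samples=100, rng=3)
        assert a.capacity == b.capacity


class TestEmpiricalOracle:
    def test_cover_regime_fully_separable(self, rng):
        # 10 points in 20 dims: load 0.5 < 2 -> essentially always separable
        ms = point_manifolds(10, 20, rng)
        stacked = np.concatenate(ms.points)
        hits = sum(linearly_separable(stacked, rng.choice([-1.0, 1.0], 10))
                   for _ in range(20))
        assert hits == 20

    def test_two_manifolds_single_feasibility(self, rng):
        ms = point_manifolds(2, 10, rng)
        out = empirical_capacity(ms, n_dichotomies=1, rng=0)
        assert isinstance(out, EmpiricalCapacity)
        assert out.fraction_separable in (0.0, 1.0)

    def test_agrees_with_mean_field_on_gaussian_points(self, rng):
        ms = point_manifolds(16, 80, rng)
        mft = mft_manifold_metrics(ms, n_samples=400, rng=2)
        emp = empirical_capacity(ms, n_dichotomies=30, rng=4)
        assert emp.capacity == pytest.approx(mft.capacity, rel=0.15)

    def test_invalid_dichotomy_count(self, rng):
        with pytest.raises(ValueError):
            empirical_capacity(point_manifolds(4, 5, rng), n_dichotomies=0)


class TestCenterCorrelation:
    def test_orthogonal_centers_near_zero(self, rng):
        # random zero-mean centers in high dimension are nearly orthogonal
        ms = point_manifolds(6, 2000, rng)
        assert center_correlation(ms) < 0.1

    def test_identical_up_to_scaling_is_one(self, rng):
        c = rng.normal(size=30)
        pts = [k * c[None, :] for k in (1.0, 2.0, 0.5)]
        ms = ManifoldSet(points=pts, labels=[0, 1, 2])
        assert center_correlation(ms) == pytest.approx(1.0)

    def test_label_permutation_invariant(self, rng):
        pts = [rng.normal(size=(4, 15)) for _ in range(5)]
        ms1 = ManifoldSet(points=pts, labels=list(range(5)))
        ms2 = ManifoldSet(points=pts[::-1], labels=list(range(5)))
        assert center_correlation(ms1) == pytest.approx(
            center_correlation(ms2))
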