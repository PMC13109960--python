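"""Twin matching on fabricated sweeps: normalization, tie-breaking,
closed-loop recovery, permutation optimality and group statistics."""

import numpy as np
import pytest

from numtwin.model import ModelConfig
from numtwin.training import SweepCheckpoint, SweepResult, TrainConfig
from numtwin.twins import (ChildRecord, DegenerateBoundsError,
                           MissingCheckpointError, NormalizationBounds,
                           compute_bounds, group_stats, match_children,
                           mean_match_distance, normalize_accuracy,
                           normalize_cohort, permutation_control,
                           select_best_iteration)


def fake_sweep(acc_by_gain_iter: dict[tuple[float, int], float]
               ) -> SweepResult:
    gains = tuple(sorted({g for g, _ in acc_by_gain_iter}))
    cps = [SweepCheckpoint(gain=g, iteration=i, test_accuracy=a,
                           response_matrix=np.zeros((19, 19), dtype=int))
           for (g, i), a in acc_by_gain_iter.items()]
    return SweepResult(checkpoints=cps,
                       train_config=TrainConfig(gains=gains),
                       model_config=ModelConfig())


UNIT_BOUNDS = dict(score_min=0.0, score_max=1.0)


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        b = NormalizationBounds(acc_min=0.1, acc_max=0.9, **UNIT_BOUNDS)
        assert normalize_accuracy(0.1, b) == 0.0
        assert normalize_accuracy(0.9, b) == 1.0
        assert normalize_accuracy(0.5, b) == pytest.approx(0.5)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(DegenerateBoundsError):
            NormalizationBounds(acc_min=0.5, acc_max=0.5, **UNIT_BOUNDS)

    def test_identical_scores_rejected(self):
        cohort = [ChildRecord(id=str(i), group="TD", numops=100.0)
                  for i in range(5)]
        with pytest.raises(DegenerateBoundsError):
            normalize_cohort(cohort)


class TestMatching:
    def test_exact_match_has_zero_distance(self):
        sweep = fake_sweep({(1.0, 100): 0.2, (2.0, 100): 0.5,
                            (3.0, 100): 0.8})
        bounds = NormalizationBounds(acc_min=0.2, acc_max=0.8, **UNIT_BOUNDS)
        cohort = [ChildRecord(id="c", group="TD", numops=0.5)]
        m, = match_children(sweep, cohort, 100, bounds)
        assert m.gain == 2.0
        assert m.distance == pytest.approx(0.0, abs=1e-12)

    def test_tie_breaks_toward_lower_gain(self):
        sweep = fake_sweep({(1.0, 0): 0.4, (2.0, 0): 0.6})
        bounds = NormalizationBounds(acc_min=0.0, acc_max=1.0, **UNIT_BOUNDS)
        cohort = [ChildRecord(id="c", group="TD", numops=0.5)]
        m, = match_children(sweep, cohort, 0, bounds)
        assert m.gain == 1.0

    def test_missing_iteration_raises(self):
        sweep = fake_sweep({(1.0, 0): 0.4})
        bounds = NormalizationBounds(acc_min=0.0, acc_max=1.0, **UNIT_BOUNDS)
        with pytest.raises(MissingCheckpointError):
            match_children(sweep, [ChildRecord("c", "TD", 0.4)], 100, bounds)

    def test_closed_loop_recovery_on_fabricated_sweep(self):
        """Children whose scores are the sweep's own normalized accuracies
        are matched back to the generating gain and iteration exactly."""
        accs = {(g, i): 0.05 + 0.9 * (i / 300) / g
                for g in (1.0, 2.0, 3.0) for i in (0, 100, 200, 300)}
        sweep = fake_sweep(accs)
        bounds = NormalizationBounds(
            acc_min=min(accs.values()), acc_max=max(accs.values()),
            **UNIT_BOUNDS)
        t_star = 200
        cohort = [ChildRecord(id=f"g{g}", group="TD",
                              numops=normalize_accuracy(accs[(g, t_star)],
                                                        bounds))
                  for g in (1.0, 2.0, 3.0)]
        matches = match_children(sweep, cohort, t_star, bounds)
        assert [m.gain for m in matches] == [1.0, 2.0, 3.0]
        assert all(m.distance == 0.0 for m in matches)
        best, table = select_best_iteration(sweep, cohort, bounds=bounds)
        assert best == t_star
        assert table.set_index("iteration").loc[t_star,
                                                "mean_distance"] == 0.0


class TestPermutationControl:
    def _matches(self):
        sweep = fake_sweep({(1.0, 0): 0.1, (2.0, 0): 0.4, (3.0, 0): 0.7,
                            (4.0, 0): 0.9})
        bounds = NormalizationBounds(acc_min=0.1, acc_max=0.9, **UNIT_BOUNDS)
        cohort = [ChildRecord(id=str(i), group="TD", numops=s)
                  for i, s in enumerate([0.05, 0.3, 0.55, 0.95, 0.7])]
        return match_children(sweep, cohort, 0, bounds)

    def test_fitted_bounds_every_permutation(self):
        matches = self._matches()
        out = permutation_control(matches, n_perm=300, rng=0)
        assert out.fitted_mean == pytest.approx(mean_match_distance(matches))
        assert (out.permuted_means >= out.fitted_mean - 1e-12).all()
        assert out.permuted_mean >= out.fitted_mean

    def test_invalid_arguments(self):
        matches = self._matches()
        with pytest.raises(ValueError):
            permutation_control(matches, n_perm=0)
        with pytest.raises(ValueError):
            permutation_control(matches[:1], n_perm=10)


class TestGroupStats:
    def test_identical_groups(self):
        out = group_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.t_statistic == 0.0 and out.cohen_d == 0.0

    def test_hand_computed_cohens_d(self):
        # {1,2,3} vs {4,5,6}: pooled SD 1, difference 3 -> d = -3
        out = group_stats([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert out.cohen_d == pytest.approx(-3.0)

    def test_zero_variance_flagged(self):
        out = group_stats([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert out.degenerate and np.isinf(out.cohen_d)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_stats([1.0], [1.0, 2.0])


class TestBoundsFromSweep:
    def test_bounds_span_all_iterations_and_gains(self):
        sweep = fake_sweep({(1.0, 0): 0.05, (1.0, 100): 0.9,
                            (2.0, 0): 0.06, (2.0, 100): 0.5})
        cohort = [ChildRecord("a", "TD", 95.0), ChildRecord("b", "MLD", 80.0)]
        b = compute_bounds(sweep, cohort)
        assert b.acc_min == 0.05 and b.acc_max == 0.9
        assert b.score_min == 80.0 and b.score_max == 95.0
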