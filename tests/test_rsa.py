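"""Representational similarity: matrix construction, canonical blocks,
operand overlap, and the Fisher-z bridge."""

import numpy as np
import pytest

from numtwin.rsa import (CoverageError, block_average, fisher_unz,
                         mean_problem_activations, nrs_matrix,
                         operand_overlap_average, predicted_vs_observed)
from numtwin.stimuli import ADD, SUB, ProblemSpec, enumerate_problems


class TestMeanProblemActivations:
    def test_single_variant_rows_equal_raw(self, rng):
        acts = rng.random((5, 7))
        out = mean_problem_activations(acts, np.arange(5), 5)
        np.testing.assert_allclose(out, acts)

    def test_duplicated_variants_leave_mean_unchanged(self, rng):
        acts = rng.random((5, 7))
        doubled = np.repeat(acts, 2, axis=0)
        pids = np.repeat(np.arange(5), 2)
        np.testing.assert_allclose(
            mean_problem_activations(doubled, pids, 5), acts)

    def test_missing_problem_raises(self, rng):
        with pytest.raises(CoverageError):
            mean_problem_activations(rng.random((3, 4)), np.array([0, 1, 1]),
                                     4)


class TestNrsMatrix:
    def test_identical_rows_correlate_to_one(self):
        specs = [ProblemSpec(0, 0, ADD), ProblemSpec(1, 1, SUB)]
        acts = np.array([[1.0, 0.0, 2.0], [2.0, 0.0, 4.0]])
        m = nrs_matrix(acts, specs).matrix
        assert m[0, 1] == pytest.approx(1.0)

    def test_hand_computed_anticorrelation(self):
        specs = [ProblemSpec(0, 0, ADD), ProblemSpec(1, 1, SUB)]
        acts = np.array([[1.0, 0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0]])
        m = nrs_matrix(acts, specs).matrix
        assert m[0, 1] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        specs = enumerate_problems(0, 3)
        acts = rng.random((len(specs), 12))
        m = nrs_matrix(acts, specs).matrix
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.nanmax(np.abs(m)) <= 1.0 + 1e-12

    def test_constant_row_flagged_not_zero_filled(self, rng):
        specs = enumerate_problems(0, 1)  # 6 problems (3 add, 3 sub)
        acts = rng.random((6, 6))
        acts[2] = 3.14
        nrs = nrs_matrix(acts, specs)
        assert np.isnan(nrs.matrix[2, 0]) and np.isnan(nrs.matrix[0, 2])
        for cat in ("add_sub", "add_add"):
            assert np.isfinite(block_average(nrs, cat))

    def test_canonical_order_additions_first(self, rng):
        specs = list(reversed(enumerate_problems(0, 2)))
        nrs = nrs_matrix(rng.random((len(specs), 8)), specs)
        ops = [s.operation for s in nrs.specs]
        assert ops == sorted(ops)  # "addition" < "subtraction"
        results = [s.result for s in nrs.specs if s.operation == ADD]
        assert results == sorted(results)


class TestBlockAverages:
    def test_constant_matrix_every_category(self, problems, rng):
        acts = rng.random(17)
        # every problem has the same activation vector -> all correlations 1
        nrs = nrs_matrix(np.tile(acts, (380, 1)), problems)
        for cat in ("add_sub", "add_add", "sub_sub"):
            assert block_average(nrs, cat) == pytest.approx(1.0)

    def test_pair_counts_on_default_task(self, problems, rng):
        nrs = nrs_matrix(rng.random((380, 10)), problems)
        a, s = nrs.add_indices, nrs.sub_indices
        assert len(a) == len(s) == 190
        assert len(a) * len(s) == 36100

    def test_unknown_category_rejected(self, problems, rng):
        nrs = nrs_matrix(rng.random((380, 5)), problems)
        with pytest.raises(ValueError):
            block_average(nrs, "mul_mul")


class TestOperandOverlap:
    def test_categories_partition_cross_pairs(self, problems, rng):
        nrs = nrs_matrix(rng.random((380, 8)), problems)
        a1 = np.array([nrs.specs[i].operand1 for i in nrs.add_indices])
        a2 = np.array([nrs.specs[i].operand2 for i in nrs.add_indices])
        b1 = np.array([nrs.specs[j].operand1 for j in nrs.sub_indices])
        b2 = np.array([nrs.specs[j].operand2 for j in nrs.sub_indices])
        both = ((a1[:, None] == b1) & (a2[:, None] == b2)).sum()
        left = ((a1[:, None] == b1) & (a2[:, None] != b2)).sum()
        right = ((a1[:, None] != b1) & (a2[:, None] == b2)).sum()
        none = ((a1[:, None] != b1) & (a2[:, None] != b2)).sum()
        assert both + left + right + none == 36100
        out = operand_overlap_average(nrs)
        assert set(out) == {"both", "left", "right", "none"}
        assert all(np.isfinite(v) for v in out.values())

    def test_example_pairs(self):
        # "6+2" vs "6-2" -> both shared; "6+2" vs "6-3" -> left only
        specs = [ProblemSpec(6, 2, ADD), ProblemSpec(6, 2, SUB),
                 ProblemSpec(6, 3, SUB)]
        acts = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 5], [4.0, 3, 2, 1]])
        nrs = nrs_matrix(acts, specs)
        out = operand_overlap_average(nrs)
        # look entries up by spec to be robust to canonical reordering
        pos = {str(s): i for i, s in enumerate(nrs.specs)}
        assert out["both"] == pytest.approx(
            nrs.matrix[pos["6+2"], pos["6-2"]])
        assert out["left"] == pytest.approx(
            nrs.matrix[pos["6+2"], pos["6-3"]])
        assert np.isnan(out["right"]) and np.isnan(out["none"])


class TestFisherBridge:
    def test_inverse_of_z_transform(self):
        assert fisher_unz(0.0) == 0.0
        assert fisher_unz(np.arctanh(0.5)) == pytest.approx(0.5)
        r = np.linspace(-0.95, 0.95, 11)
        np.testing.assert_allclose(fisher_unz(np.arctanh(r)), r, atol=1e-12)


class TestPredictedVsObserved:
    def test_identity_gives_r_one(self, rng):
        x = rng.uniform(0.1, 0.8, 20)
        r, null = predicted_vs_observed(x, x, n_perm=200, rng=rng)
        assert r == pytest.approx(1.0)
        assert abs(null.mean()) < 0.1

    def test_independent_observations_null_centered(self, rng):
        x = rng.uniform(0.1, 0.8, 45)
        y = rng.uniform(0.1, 0.8, 45)
        _, null = predicted_vs_observed(x, y, n_perm=500, rng=rng)
        assert abs(null.mean()) < 0.05

    def test_attenuation_recovery(self, rng):
        """With z-scale coupling 1 and noise sd matched to the predictor
        spread, expected r is 1/sqrt(2); a large cohort recovers it."""
        from numtwin.cohort import generate_observed_nrs
        z = rng.normal(0.4, 0.3, size=4000)
        predicted = np.tanh(z)
        observed = generate_observed_nrs(predicted, coupling=1.0,
                                         noise_sd=np.std(z), rng=rng)
        r, _ = predicted_vs_observed(predicted, observed, n_perm=10, rng=rng)
        assert r == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_too_few_children_rejected(self):
        with pytest.raises(ValueError):
            predicted_vs_observed(np.array([0.1, 0.2]), np.array([0.1, 0.2]))
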