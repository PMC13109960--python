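"""Problem enumeration, glyph synthesis and dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from numtwin.stimuli import (ADD, SUB, GlyphBank, ProblemSpec, build_dataset,
                             build_glyph_bank, enumerate_problems,
                             problem_characters, render_problem)


class TestEnumeration:
    def test_default_task_has_380_balanced_problems(self, problems):
        assert len(problems) == 380
        assert sum(p.operation == ADD for p in problems) == 190
        assert sum(p.operation == SUB for p in problems) == 190
        per_result = np.bincount([p.result for p in problems], minlength=19)
        assert (per_result == 20).all()
        assert len(set(problems)) == 380  # no duplicates

    def test_results_and_operands_bounded(self, problems):
        for p in problems:
            assert 0 <= p.result <= 18
            assert 0 <= p.operand1 <= 18 and 0 <= p.operand2 <= 18

    def test_tiny_addition_case(self):
        got = enumerate_problems(0, 1, {ADD})
        assert {(p.operand1, p.operand2) for p in got} == {(0, 0), (0, 1),
                                                           (1, 0)}

    def test_deterministic_order(self):
        assert enumerate_problems() == enumerate_problems()

    def test_empty_operations_rejected(self):
        with pytest.raises(ValueError):
            enumerate_problems(operations=())

    @given(bound=hst.integers(min_value=0, max_value=18))
    @settings(deadline=None, derandomize=True, max_examples=19)
    def test_addition_count_closed_form(self, bound):
        # ordered pairs with a+b <= R number (R+1)(R+2)/2
        got = enumerate_problems(0, bound, {ADD})
        assert len(got) == (bound + 1) * (bound + 2) // 2


class TestGlyphBank:
    def test_blank_is_all_zero(self, small_bank):
        assert small_bank.glyphs["blank"].shape[1:] == (3, 28, 28)
        assert not small_bank.glyphs["blank"].any()

    def test_same_seed_is_bit_identical(self):
        a = build_glyph_bank(n_variants=3, rng_seed=11)
        b = build_glyph_bank(n_variants=3, rng_seed=11)
        for char in a.glyphs:
            np.testing.assert_array_equal(a.glyphs[char], b.glyphs[char])

    def test_variants_are_distinct(self, small_bank):
        for char, pool in small_bank.glyphs.items():
            if char == "blank":
                continue
            flat = pool.reshape(pool.shape[0], -1)
            for i in range(len(flat)):
                for j in range(i + 1, len(flat)):
                    assert not np.array_equal(flat[i], flat[j]), char

    def test_intensities_in_unit_interval(self, small_bank):
        for pool in small_bank.glyphs.values():
            assert pool.min() >= 0.0 and pool.max() <= 1.0

    @pytest.mark.parametrize("style", ["printed", "mixed"])
    def test_alternate_styles_render(self, style):
        bank = build_glyph_bank(style, n_variants=2, rng_seed=0)
        assert bank.glyphs["7"].any()

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError):
            build_glyph_bank("cursive", n_variants=2)


class TestRendering:
    def test_five_slot_layout(self):
        # "10-2": tens1="1", units1="0", minus, tens2=blank, units2="2"
        assert problem_characters(ProblemSpec(10, 2, SUB)) == \
            ["1", "0", "minus", "blank", "2"]
        assert problem_characters(ProblemSpec(0, 0, ADD)) == \
            ["blank", "0", "plus", "blank", "0"]

    def test_rendered_shape_and_blank_slots(self, small_bank, rng):
        img = render_problem(ProblemSpec(10, 2, SUB), small_bank, rng)
        assert img.shape == (3, 28, 140)
        assert img[:, :, :28].any()            # tens1 = "1"
        assert not img[:, :, 84:112].any()     # tens2 blank
        img0 = render_problem(ProblemSpec(0, 0, ADD), small_bank, rng)
        assert not img0[:, :, :28].any() and not img0[:, :, 84:112].any()

    def test_large_operand_rejected(self, small_bank, rng):
        with pytest.raises(ValueError):
            render_problem(ProblemSpec(100, 82, ADD), small_bank, rng)


class TestDataset:
    def test_split_balance_and_shapes(self, tiny_dataset):
        assert tiny_dataset.images.shape[1:] == (3, 28, 140)
        assert tiny_dataset.is_train.sum() == len(tiny_dataset.labels) // 2
        # every problem has equal train and test variant counts
        for pid in np.unique(tiny_dataset.problem_ids):
            mask = tiny_dataset.problem_ids == pid
            assert tiny_dataset.is_train[mask].sum() == mask.sum() // 2

    def test_per_result_counts_equal_within_split(self, small_bank):
        problems = enumerate_problems()
        ds = build_dataset(problems[:0] + problems, small_bank,
                           variants_per_problem=2, rng_seed=0)
        train_counts = np.bincount(ds.labels[ds.train_indices], minlength=19)
        assert (train_counts == 20).all()      # 20 problems x 1 variant

    def test_train_test_disjoint_by_hash(self, tiny_dataset):
        import hashlib

        def hashes(idx):
            return {hashlib.sha1(tiny_dataset.images[i].tobytes())
                    .hexdigest() for i in idx}
        assert not hashes(tiny_dataset.train_indices) & \
            hashes(tiny_dataset.test_indices)

    def test_seed_determinism(self, small_bank):
        probs = enumerate_problems(0, 2)
        a = build_dataset(probs, small_bank, 2, rng_seed=9)
        b = build_dataset(probs, small_bank, 2, rng_seed=9)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.is_train, b.is_train)

    def test_odd_variants_rejected(self, small_bank):
        with pytest.raises(ValueError):
            build_dataset(enumerate_problems(0, 1), small_bank, 3)

    def test_hdf5_roundtrip(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.h5"
        tiny_dataset.save(str(path))
        loaded = type(tiny_dataset).load(str(path))
        np.testing.assert_array_equal(loaded.images, tiny_dataset.images)
        np.testing.assert_array_equal(loaded.is_train, tiny_dataset.is_train)
        assert loaded.problems == tiny_dataset.problems
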