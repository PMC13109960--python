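"""Shared fixtures.

The desk-scale gain sweep (5 gains x 600 iterations on a reduced-width
model) is the study's scaled-down analogue of the full training protocol and
is expensive; it is built once per session and shared by the behavioral,
representational and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from numtwin.model import GAIN_GRID_DESK, ModelConfig
from numtwin.stimuli import (build_dataset, build_glyph_bank,
                             enumerate_problems)
from numtwin.training import TrainConfig, train_sweep

DESK_SEED = 7
DESK_MID_ITERATION = 300
DESK_FINAL_ITERATION = 500


@pytest.fixture(scope="session")
def problems():
    return enumerate_problems()


@pytest.fixture(scope="session")
def small_bank():
    return build_glyph_bank("handwritten_synthetic", n_variants=12,
                            rng_seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(small_bank):
    """2 problems per result (one addition, one subtraction), 2 variants."""
    chosen = []
    for r in range(19):
        adds = [p for p in enumerate_problems(operations=("addition",))
                if p.result == r]
        subs = [p for p in enumerate_problems(operations=("subtraction",))
                if p.result == r]
        chosen += [adds[0], subs[0]]
    return build_dataset(chosen, small_bank, variants_per_problem=2,
                         rng_seed=5)


@pytest.fixture(scope="session")
def desk_dataset(problems):
    bank = build_glyph_bank("handwritten_synthetic", n_variants=100,
                            rng_seed=DESK_SEED)
    return build_dataset(problems, bank, variants_per_problem=40,
                         rng_seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_model_config():
    return ModelConfig(scale_profile="desk", rng_seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_train_config():
    return TrainConfig(gains=GAIN_GRID_DESK,
                       max_iterations=DESK_FINAL_ITERATION, eval_every=100,
                       rng_seed=DESK_SEED,
                       capture_iterations=(DESK_FINAL_ITERATION,))


@pytest.fixture(scope="session")
def desk_sweep(desk_dataset, desk_train_config, desk_model_config):
    return train_sweep(desk_dataset, desk_train_config, desk_model_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
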