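"""Problem-level representational similarity analysis (RSA).

For one layer, the neural representational similarity (NRS) matrix holds the
Pearson correlation — computed across units — between the mean activation
patterns evoked by every pair of the 380 problems.  Rows/columns follow a
canonical order: additions before subtractions, then ascending result, then
ascending first operand.  Block averages summarize the similarity between
operations (add-sub) and within operations (add-add, sub-sub, excluding the
trivial unit diagonal); an operand-overlap analysis splits the cross-operation
pairs by which operands the two problems share.  ``fisher_unz`` (tanh) maps
Fisher-z values back to the correlation scale so model NRS can be compared
with externally measured similarity values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stimuli import ADD, SUB, ProblemSpec, problem_order_key


class CoverageError(ValueError):
    """Some problem has no activations to average."""


def mean_problem_activations(activations: np.ndarray,
                             problem_ids: np.ndarray,
                             n_problems: int) -> np.ndarray:
    """Row p = unit-wise mean activation over all variants of problem p."""
    activations = np.asarray(activations, dtype=np.float64)
    sums = np.zeros((n_problems, activations.shape[1]))
    counts = np.zeros(n_problems, dtype=np.int64)
    np.add.at(sums, problem_ids, activations)
    np.add.at(counts, problem_ids, 1)
    if (counts == 0).any():
        raise CoverageError(
            f"problems without activations: {np.flatnonzero(counts == 0)[:10]}")
    return sums / counts[:, None]


@dataclass
class NRSMatrix:
    """Similarity matrix in canonical problem order.

    Entries involving a constant (zero-variance) activation row are NaN and
    are excluded from every average.
    """

    matrix: np.ndarray                  # (P, P), NaN where undefined
    specs: list[ProblemSpec]            # canonical order
    layer: str = ""

    @property
    def add_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.specs)
                         if s.operation == ADD])

    @property
    def sub_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.specs)
                         if s.operation == SUB])


def nrs_matrix(mean_acts: np.ndarray, specs: Sequence[ProblemSpec],
               layer: str = "", max_units: int = 8192,
               rng_seed: int = 0) -> NRSMatrix:
    """Pearson correlation across units between mean problem activations.

    Layers wider than ``max_units`` are unit-subsampled with the recorded
    seed before correlating, for tractability.
    """
    mean_acts = np.asarray(mean_acts, dtype=np.float64)
    if len(specs) != mean_acts.shape[0]:
        raise ValueError("one activation row per problem required")
    order = sorted(range(len(specs)), key=lambda i: problem_order_key(specs[i]))
    specs_sorted = [specs[i] for i in order]
    acts = mean_acts[order]
    if acts.shape[1] > max_units:
        rng = np.random.default_rng(rng_seed)
        cols = rng.choice(acts.shape[1], size=max_units, replace=False)
        acts = acts[:, np.sort(cols)]
    if acts.shape[1] < 2:
        raise ValueError("need >= 2 units to correlate across")
    centered = acts - acts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    m = np.full((len(specs), len(specs)), np.nan)
    if valid.any():
        c = centered[valid] / norms[valid, None]
        block = np.clip(c @ c.T, -1.0, 1.0)
        m[np.ix_(valid, valid)] = block
        np.fill_diagonal(block, 1.0)
        m[np.ix_(valid, valid)] = block
    return NRSMatrix(matrix=m, specs=specs_sorted, layer=layer)


BLOCK_CATEGORIES = ("add_sub", "add_add", "sub_sub")


def block_average(nrs: NRSMatrix, category: str) -> float:
    """Mean similarity over a pair category (within-operation averages
    exclude self-pairs)."""
    if category not in BLOCK_CATEGORIES:
        raise ValueError(f"category must be one of {BLOCK_CATEGORIES}")
    a, s = nrs.add_indices, nrs.sub_indices
    if category == "add_sub":
        if len(a) == 0 or len(s) == 0:
            raise ValueError("category has no pairs")
        vals = nrs.matrix[np.ix_(a, s)].ravel()
    else:
        idx = a if category == "add_add" else s
        if len(idx) < 2:
            raise ValueError("category has no pairs")
        sub = nrs.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
    return float(np.nanmean(vals))


OVERLAP_CATEGORIES = ("both", "left", "right", "none")


def operand_overlap_average(nrs: NRSMatrix) -> dict[str, float]:
    """Mean cross-operation similarity by operand overlap.

    Every (addition, subtraction) pair lands in exactly one category:
    ``both`` operands shared (e.g. 6+2 vs 6-2), only the ``left`` or only the
    ``right`` operand shared, or ``none``.
    """
    a_idx, s_idx = nrs.add_indices, nrs.sub_indices
    a1 = np.array([nrs.specs[i].operand1 for i in a_idx])
    a2 = np.array([nrs.specs[i].operand2 for i in a_idx])
    b1 = np.array([nrs.specs[j].operand1 for j in s_idx])
    b2 = np.array([nrs.specs[j].operand2 for j in s_idx])
    left = a1[:, None] == b1[None, :]
    right = a2[:, None] == b2[None, :]
    cat = np.where(left & right, 0,
                   np.where(left, 1, np.where(right, 2, 3)))
    block = nrs.matrix[np.ix_(a_idx, s_idx)]
    return {name: float(np.nanmean(block[cat == i]))
            for i, name in enumerate(OVERLAP_CATEGORIES)}


def fisher_unz(z) -> np.ndarray | float:
    """Inverse Fisher z-transform: tanh, mapping z-values to (-1, 1)."""
    return np.tanh(z)


def predicted_vs_observed(predicted: np.ndarray, observed: np.ndarray,
                          n_perm: int = 1000,
                          rng: np.random.Generator | None = None
                          ) -> tuple[float, np.ndarray]:
    """Pearson r between per-child predicted and observed NRS, plus a
    permutation-null distribution of r under random child reassignment."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be matching 1-d arrays")
    if len(predicted) < 3:
        raise ValueError("need at least 3 children")
    rng = rng or np.random.default_rng()

    def _pearson(x, y):
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.linalg.norm(xc) * np.linalg.norm(yc)
        if denom == 0:
            return np.nan
        return float(xc @ yc / denom)

    r = _pearson(predicted, observed)
    null = np.array([_pearson(predicted, rng.permutation(observed))
                     for _ in range(n_perm)])
    return r, null
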