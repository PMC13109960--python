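"""Scalar behavioral measures derived from the response-count matrix.

The response matrix ``counts[s, r]`` holds how often the model answered ``r``
when the true result was ``s`` (both 0..18).  From it we compute accuracy,
numerical systematic error (trueness: how far the average answer sits from
the true result, averaged over result levels), numerical imprecision
(precision: the within-level standard deviation of answers, averaged over
levels) and the effective number of distinct responses, measured as the
exponential of the natural-log Shannon entropy of the pooled answer
distribution — exactly ``k`` for a uniform distribution over ``k`` answers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class UndefinedLevelError(ValueError):
    """A true-result level received no responses; level means are undefined."""


def _validate(counts: np.ndarray, require_all_levels: bool) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("response matrix must be square (true x response)")
    if (counts < 0).any():
        raise ValueError("response counts must be non-negative")
    if require_all_levels and (counts.sum(axis=1) == 0).any():
        missing = np.flatnonzero(counts.sum(axis=1) == 0).tolist()
        raise UndefinedLevelError(f"no responses at result level(s) {missing}")
    return counts


def accuracy(counts: np.ndarray) -> float:
    counts = _validate(counts, require_all_levels=False)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty response matrix")
    return float(np.trace(counts) / total)


def systematic_error(counts: np.ndarray) -> float:
    """Mean over result levels of |mean response - true result|."""
    counts = _validate(counts, require_all_levels=True)
    values = np.arange(counts.shape[1], dtype=np.float64)
    level_totals = counts.sum(axis=1)
    level_means = counts @ values / level_totals
    true_values = np.arange(counts.shape[0], dtype=np.float64)
    return float(np.mean(np.abs(level_means - true_values)))


def imprecision(counts: np.ndarray) -> float:
    """Mean over result levels of the population SD of responses."""
    counts = _validate(counts, require_all_levels=True)
    values = np.arange(counts.shape[1], dtype=np.float64)
    level_totals = counts.sum(axis=1)
    m1 = counts @ values / level_totals
    m2 = counts @ values**2 / level_totals
    var = np.maximum(m2 - m1**2, 0.0)
    return float(np.mean(np.sqrt(var)))


def effective_num_responses(counts: np.ndarray) -> float:
    """exp(Shannon entropy, natural log) of the pooled answer distribution."""
    counts = _validate(counts, require_all_levels=False)
    pooled = counts.sum(axis=0).astype(np.float64)
    total = pooled.sum()
    if total == 0:
        raise ValueError("empty response matrix")
    p = pooled[pooled > 0] / total
    return float(np.exp(-np.sum(p * np.log(p))))


def metrics_table(sweep) -> pd.DataFrame:
    """All behavioral measures for every (gain, iteration) checkpoint."""
    rows = []
    for c in sweep.checkpoints:
        rows.append({
            "gain": c.gain,
            "iteration": c.iteration,
            "accuracy": accuracy(c.response_matrix),
            "systematic_error": systematic_error(c.response_matrix),
            "imprecision": imprecision(c.response_matrix),
            "effective_num_responses":
                effective_num_responses(c.response_matrix),
        })
    return (pd.DataFrame(rows)
            .sort_values(["gain", "iteration"]).reset_index(drop=True))
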