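"""Digital-twin matching between children and gain-swept models.

Children's standard scores and model accuracies are each min-max normalized
to [0, 1] — the score bounds over the cohort, the accuracy bounds over *all*
iterations and gains of the sweep — and compared with the L1 distance
``|A_norm - NO_norm|``.  For each child, the gain minimizing that distance at
a given iteration is the child's personalized model; the best-matching
iteration minimizes the mean per-child distance over the evaluation grid.  A
permutation control reassigns children's scores across the fitted models to
show the fit is better than chance pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


MLD_CUTOFF = 90.0


@dataclass(frozen=True)
class ChildRecord:
    id: str
    group: str                      # "TD" | "MLD"
    numops: float                   # standard-score scale
    normalized_numops: float = float("nan")


class DegenerateBoundsError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationBounds:
    acc_min: float
    acc_max: float
    score_min: float
    score_max: float

    def __post_init__(self) -> None:
        if not (self.acc_min < self.acc_max):
            raise DegenerateBoundsError("accuracy bounds are degenerate")
        if not (self.score_min < self.score_max):
            raise DegenerateBoundsError("score bounds are degenerate")


def compute_bounds(sweep, cohort: list[ChildRecord]) -> NormalizationBounds:
    """Accuracy extremes across the whole sweep; score extremes across the
    cohort.  Computed once, before any matching."""
    accs = [c.test_accuracy for c in sweep.checkpoints]
    scores = [ch.numops for ch in cohort]
    return NormalizationBounds(acc_min=min(accs), acc_max=max(accs),
                               score_min=min(scores), score_max=max(scores))


def normalize_accuracy(accuracy: float, bounds: NormalizationBounds) -> float:
    return (accuracy - bounds.acc_min) / (bounds.acc_max - bounds.acc_min)


def normalize_cohort(cohort: list[ChildRecord],
                     bounds: NormalizationBounds | None = None
                     ) -> list[ChildRecord]:
    """Fill in min-max normalized scores (cohort-wide extremes)."""
    scores = np.array([c.numops for c in cohort], dtype=np.float64)
    if bounds is None:
        if scores.max() == scores.min():
            raise DegenerateBoundsError("all children share one score")
        lo, hi = scores.min(), scores.max()
    else:
        lo, hi = bounds.score_min, bounds.score_max
    return [replace(c, normalized_numops=float((c.numops - lo) / (hi - lo)))
            for c in cohort]


@dataclass
class TwinMatch:
    child_id: str
    group: str
    iteration: int
    gain: float
    normalized_accuracy: float
    normalized_score: float
    distance: float
    predicted_nrs: float = float("nan")


class MissingCheckpointError(KeyError):
    pass


def match_children(sweep, cohort: list[ChildRecord], iteration: int,
                   bounds: NormalizationBounds) -> list[TwinMatch]:
    """Per child, the gain minimizing |A_norm - NO_norm| at the iteration.

    Ties break toward the lowest gain.
    """
    cps = sorted((c for c in sweep.checkpoints if c.iteration == iteration),
                 key=lambda c: c.gain)
    if not cps:
        raise MissingCheckpointError(f"no checkpoints at iteration {iteration}")
    gains = np.array([c.gain for c in cps])
    norm_acc = np.array([normalize_accuracy(c.test_accuracy, bounds)
                         for c in cps])
    cohort = normalize_cohort(cohort, bounds)
    matches = []
    for child in cohort:
        d = np.abs(norm_acc - child.normalized_numops)
        best = int(np.argmin(d))        # argmin returns the first (lowest G)
        matches.append(TwinMatch(
            child_id=child.id, group=child.group, iteration=iteration,
            gain=float(gains[best]),
            normalized_accuracy=float(norm_acc[best]),
            normalized_score=child.normalized_numops,
            distance=float(d[best])))
    return matches


def mean_match_distance(matches: list[TwinMatch]) -> float:
    return float(np.mean([m.distance for m in matches]))


def select_best_iteration(sweep, cohort: list[ChildRecord],
                          iterations: list[int] | None = None,
                          bounds: NormalizationBounds | None = None
                          ) -> tuple[int, pd.DataFrame]:
    """Iteration with the smallest mean per-child best-match distance."""
    if iterations is None:
        iterations = sweep.iterations
    if not iterations:
        raise ValueError("iteration grid must be non-empty")
    bounds = bounds or compute_bounds(sweep, cohort)
    rows = []
    for it in iterations:
        rows.append({"iteration": it,
                     "mean_distance": mean_match_distance(
                         match_children(sweep, cohort, it, bounds))})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["mean_distance"].idxmin(), "iteration"])
    return best, table


@dataclass
class PermutationControl:
    fitted_mean: float
    permuted_mean: float
    permuted_sd: float
    permuted_means: np.ndarray
    t_statistic: float
    p_value: float


def permutation_control(matches: list[TwinMatch], n_perm: int = 1000,
                        rng: np.random.Generator | int | None = None
                        ) -> PermutationControl:
    """Distance under random reassignment of children's scores to the fitted
    models.  The fitted mean is a lower bound on every permutation's mean."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(matches) < 2:
        raise ValueError("need at least 2 children")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    acc = np.array([m.normalized_accuracy for m in matches])
    scores = np.array([m.normalized_score for m in matches])
    fitted = float(np.mean(np.abs(acc - scores)))
    perm_means = np.array([
        float(np.mean(np.abs(acc - rng.permutation(scores))))
        for _ in range(n_perm)])
    t, p = stats.ttest_1samp(perm_means, fitted)
    return PermutationControl(
        fitted_mean=fitted, permuted_mean=float(perm_means.mean()),
        permuted_sd=float(perm_means.std(ddof=1)) if n_perm > 1 else 0.0,
        permuted_means=perm_means, t_statistic=float(t), p_value=float(p))


@dataclass
class GroupStats:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    cohen_d: float
    degenerate: bool


def group_stats(values_a, values_b) -> GroupStats:
    """Welch two-sample t-test plus pooled-SD Cohen's d."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                      + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
    degenerate = pooled == 0
    if degenerate:
        d = 0.0 if a.mean() == b.mean() else float("inf")
        d *= np.sign(a.mean() - b.mean()) or 1.0
    else:
        d = float((a.mean() - b.mean()) / pooled)
    return GroupStats(mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                      mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                      t_statistic=float(t), p_value=float(p), cohen_d=d,
                      degenerate=bool(degenerate))


def matches_table(matches: list[TwinMatch]) -> pd.DataFrame:
    return pd.DataFrame([{
        "child_id": m.child_id, "group": m.group, "iteration": m.iteration,
        "gain": m.gain, "normalized_accuracy": m.normalized_accuracy,
        "normalized_score": m.normalized_score, "distance": m.distance,
        "predicted_nrs": m.predicted_nrs} for m in matches])
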