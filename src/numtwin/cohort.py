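"""Synthetic child cohort.

Stands in for a study cohort of 45 children (24 typically developing, 21
with mathematical learning difficulties, defined by a standard score below
90) whose min-max-normalized achievement scores have group means near 0.70
(TD) and 0.35 (MLD).  Scores are drawn on the standard-score scale as a
mixture of a truncated-normal bulk and a small uniform "range" component
spanning each group's full score range; the uniform component keeps the
cohort extremes stable so min-max normalization is well conditioned, the way
a real cohort's scattered outliers anchor its observed range.  The bulk
location is calibrated by root finding so the asymptotic normalized group
mean hits the configured target exactly.

``generate_observed_nrs`` fabricates per-child "observed" neural similarity
values from model-predicted ones through a Fisher-z linear coupling with
Gaussian noise, for exercising the prediction-correlation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .twins import ChildRecord, MLD_CUTOFF


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    n_td: int = 24
    n_mld: int = 21
    td_norm_mean: float = 0.70
    td_norm_sd: float = 0.13
    mld_norm_mean: float = 0.35
    mld_norm_sd: float = 0.06
    mld_cutoff: float = MLD_CUTOFF
    score_min: float = 55.0         # attainable floor of the score range
    score_max: float = 130.0        # attainable ceiling
    range_fraction: float = 0.1     # weight of the uniform range component
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_td < 1 or self.n_mld < 1:
            raise CalibrationError("group sizes must be >= 1")
        if not (self.score_min < self.mld_cutoff < self.score_max):
            raise CalibrationError("cutoff must lie inside the score range")
        if not (0.0 <= self.range_fraction < 1.0):
            raise CalibrationError("range_fraction must lie in [0, 1)")

    @property
    def scale(self) -> float:
        return self.score_max - self.score_min

    def to_raw(self, normalized: float) -> float:
        return self.score_min + normalized * self.scale


def _truncnorm_mean(loc: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))


def _calibrate_loc(target_mean: float, sd: float, lo: float, hi: float,
                   mix: float) -> float:
    """Bulk location such that the bulk/uniform mixture mean equals target."""
    uniform_mean = 0.5 * (lo + hi)

    def gap(loc: float) -> float:
        bulk = _truncnorm_mean(loc, sd, lo, hi)
        return (1.0 - mix) * bulk + mix * uniform_mean - target_mean

    span = hi - lo
    left, right = lo - 2 * sd, hi + 2 * sd
    if gap(left) > 0 or gap(right) < 0:
        raise CalibrationError(
            f"target mean {target_mean} unreachable on [{lo}, {hi}] "
            f"with sd {sd} and range fraction {mix}")
    return float(brentq(gap, left, right, xtol=1e-10 * span))


def generate_cohort(config: CohortConfig = CohortConfig(),
                    rng: np.random.Generator | None = None
                    ) -> list[ChildRecord]:
    """Draw the cohort; group labels are consistent with the cutoff by
    construction and generation is deterministic given the seed."""
    rng = rng or np.random.default_rng(config.rng_seed)
    records: list[ChildRecord] = []
    groups = (
        ("MLD", config.n_mld, config.mld_norm_mean, config.mld_norm_sd,
         config.score_min, config.mld_cutoff),
        ("TD", config.n_td, config.td_norm_mean, config.td_norm_sd,
         config.mld_cutoff, config.score_max),
    )
    for group, n, norm_mean, norm_sd, lo, hi in groups:
        target = config.to_raw(norm_mean)
        if not (lo < target < hi):
            raise CalibrationError(
                f"{group} target mean {target} outside its range [{lo}, {hi}]")
        sd = norm_sd * config.scale
        loc = _calibrate_loc(target, sd, lo, hi, config.range_fraction)
        a, b = (lo - loc) / sd, (hi - loc) / sd
        bulk = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n,
                                   random_state=rng)
        uniform = rng.uniform(lo, hi, size=n)
        from_range = rng.random(n) < config.range_fraction
        scores = np.where(from_range, uniform, bulk)
        # keep MLD strictly below the cutoff
        if group == "MLD":
            scores = np.minimum(scores, np.nextafter(config.mld_cutoff,
                                                     -np.inf))
        records.extend(
            ChildRecord(id=f"{group.lower()}{i:03d}", group=group,
                        numops=float(s))
            for i, s in enumerate(scores))
    return records


def generate_observed_nrs(predicted: np.ndarray, coupling: float,
                          noise_sd: float,
                          rng: np.random.Generator | None = None
                          ) -> np.ndarray:
    """Synthetic observed NRS: tanh(coupling * atanh(predicted) + noise).

    Inputs and outputs live on the correlation scale (-1, 1); the coupling
    acts on the Fisher-z scale.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    if np.any(np.abs(predicted) >= 1.0):
        raise ValueError("predicted NRS must lie strictly inside (-1, 1)")
    rng = rng or np.random.default_rng()
    z = coupling * np.arctanh(predicted)
    z = z + rng.normal(0.0, noise_sd, size=predicted.shape)
    return np.tanh(z)
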