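"""Geometry of the result manifolds.

The 380 mean problem activations of a layer form 19 "result manifolds" — one
group of 20 points per possible answer.  Their linear separability is
summarized by the mean-field manifold capacity: the number of manifolds per
unit dimension at which a random balanced dichotomy of manifolds transitions
from linearly separable to non-separable.  For zero-radius (point) manifolds
with uncorrelated centers this recovers the classical function-counting limit
of 2 points per dimension.

The mean-field estimate follows the replica-theory algorithm: each manifold
is expressed in its own ``D+1``-dimensional frame (D principal axes of the
centered points, plus the center direction with the axes rescaled by the
center norm), and for Gaussian probe vectors ``T`` the inverse capacity is
the average squared distance from ``T`` to the convex cone
``{V : V . s <= -kappa for all manifold points s}``.  At margin ``kappa = 0``
that projection is computed exactly via non-negative least squares (Moreau
decomposition); the anchor-point statistics of the same projections yield the
manifold radius and dimensionality.  An independent empirical oracle checks
linear separability of random dichotomies directly with LP feasibility and
locates the 50%-separable projection dimension by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog, minimize, nnls

from .stimuli import ProblemSpec


class CoverageError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class ManifoldSet:
    """Groups of unit-space points, one group per result value."""

    points: list[np.ndarray]        # each (m_i, n_units)
    labels: list[int]               # result value per manifold
    layer: str = ""

    @property
    def n_manifolds(self) -> int:
        return len(self.points)

    @property
    def ambient_dim(self) -> int:
        return self.points[0].shape[1]

    def centers(self) -> np.ndarray:
        return np.stack([p.mean(axis=0) for p in self.points])


def group_by_result(mean_acts: np.ndarray, specs: Sequence[ProblemSpec],
                    expected_results: Sequence[int] | None = range(19),
                    layer: str = "") -> ManifoldSet:
    """One manifold per result value; problems sharing a result share a
    manifold (e.g. 2+7, 5+4 and 9-0 all belong to manifold 9)."""
    mean_acts = np.asarray(mean_acts, dtype=np.float64)
    if len(specs) != mean_acts.shape[0]:
        raise ValueError("one activation row per problem required")
    results = np.array([s.result for s in specs])
    present = sorted(set(results.tolist()))
    if expected_results is not None:
        missing = sorted(set(expected_results) - set(present))
        if missing:
            raise CoverageError(f"no problems for result value(s) {missing}")
        present = sorted(expected_results)
    points = [mean_acts[results == r] for r in present]
    return ManifoldSet(points=points, labels=list(present), layer=layer)


@dataclass
class ManifoldMetrics:
    capacity: float
    dimension: float
    radius: float
    center_correlation: float
    per_manifold_inverse_capacity: np.ndarray
    per_manifold_dimension: np.ndarray
    per_manifold_radius: np.ndarray


def _cone_projection_residual(s_tilde: np.ndarray, t: np.ndarray,
                              kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Project t onto {V : s_tilde @ V <= -kappa}; return (lambda, t - V).

    For kappa = 0 the dual is exactly an NNLS problem; otherwise the
    non-negative quadratic dual is solved with L-BFGS-B.
    """
    a = s_tilde.T                                   # (D+1, m)
    if np.all(s_tilde @ t <= -kappa + 1e-12):
        return np.zeros(s_tilde.shape[0]), np.zeros_like(t)
    if kappa == 0.0:
        lam, _ = nnls(a, t)
    else:
        q = s_tilde @ s_tilde.T
        lin = s_tilde @ t + kappa

        def obj(lam):
            qlam = q @ lam
            return 0.5 * lam @ qlam - lam @ lin, qlam - lin

        res = minimize(obj, np.zeros(s_tilde.shape[0]), jac=True,
                       method="L-BFGS-B",
                       bounds=[(0, None)] * s_tilde.shape[0])
        lam = res.x
    return lam, a @ lam


def mft_manifold_metrics(ms: ManifoldSet, kappa: float = 0.0,
                         n_samples: int = 200,
                         rng: np.random.Generator | int | None = 0,
                         max_dim: int = 500,
                         subtract_global_mean: bool = True
                         ) -> ManifoldMetrics:
    """Replica mean-field capacity, dimensionality and radius.

    Deterministic given the seed.  Ambient spaces wider than ``max_dim`` are
    first reduced by a seeded Gaussian random projection.  The global mean
    activation is subtracted first (default): a large shared response
    component otherwise inflates every center norm and masks the geometry
    the per-manifold theory measures.  The reported ``center_correlation``
    is always computed on the raw centers.
    """
    if ms.n_manifolds < 2:
        raise ValueError("need at least 2 manifolds")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    pts = [np.asarray(p, dtype=np.float64) for p in ms.points]
    spread = np.ptp(np.concatenate(pts), axis=0)
    if not np.any(spread > 0):
        raise DegenerateGeometryError("all points are identical")
    n = pts[0].shape[1]
    if n > max_dim:
        proj = rng.normal(0.0, 1.0 / np.sqrt(max_dim), size=(n, max_dim))
        pts = [p @ proj for p in pts]
    if subtract_global_mean:
        gmean = np.concatenate(pts).mean(axis=0)
        pts = [p - gmean for p in pts]

    inv_caps, dims, radii = [], [], []
    for p in pts:
        c = p.mean(axis=0)
        centered = p - c
        # manifold frame: principal axes of the centered points
        if p.shape[0] > 1 and np.any(np.abs(centered) > 0):
            u, sv, vt = np.linalg.svd(centered, full_matrices=False)
            rank = int(np.sum(sv > 1e-10 * max(sv.max(), 1e-30)))
        else:
            rank = 0
        norm_c = np.linalg.norm(c)
        if norm_c < 1e-12:
            norm_c = 1.0
        if rank > 0:
            coords = (u[:, :rank] * sv[:rank]) / norm_c      # (m, D)
            s_tilde = np.hstack([coords, np.ones((p.shape[0], 1))])
        else:
            s_tilde = np.ones((p.shape[0], 1))
        d1 = s_tilde.shape[1]

        f_vals, d_vals, r_vals = [], [], []
        for _ in range(n_samples):
            t = rng.normal(size=d1)
            lam, w = _cone_projection_residual(s_tilde, t, kappa)
            f_vals.append(float(w @ w))
            lam_sum = lam.sum()
            if lam_sum > 1e-12 and d1 > 1:
                anchor = (s_tilde.T @ lam) / lam_sum
                axes = anchor[:-1]
                norm_axes = np.linalg.norm(axes)
                r_vals.append(norm_axes)
                if norm_axes > 1e-12:
                    d_vals.append(float((t[:-1] @ axes / norm_axes) ** 2))
        inv_caps.append(float(np.mean(f_vals)))
        dims.append(float(np.mean(d_vals)) if d_vals else 0.0)
        radii.append(float(np.mean(r_vals)) if r_vals else 0.0)

    inv_caps = np.array(inv_caps)
    mean_inv = float(np.mean(inv_caps))
    return ManifoldMetrics(
        capacity=1.0 / mean_inv if mean_inv > 0 else np.inf,
        dimension=float(np.mean(dims)),
        radius=float(np.mean(radii)),
        center_correlation=center_correlation(ms),
        per_manifold_inverse_capacity=inv_caps,
        per_manifold_dimension=np.array(dims),
        per_manifold_radius=np.array(radii))


# -- empirical separability oracle ------------------------------------------

def _balanced_dichotomy(p: int, rng: np.random.Generator) -> np.ndarray:
    half = p // 2
    signs = np.full(p, -1.0)
    signs[rng.choice(p, size=half + (p % 2) * int(rng.integers(2)),
                     replace=False)] = 1.0
    return signs


def linearly_separable(points: np.ndarray, signs: np.ndarray) -> bool:
    """LP feasibility of a homogeneous hyperplane with unit margin."""
    a_ub = -(signs[:, None] * points)
    b_ub = -np.ones(points.shape[0])
    res = linprog(c=np.zeros(points.shape[1]), A_ub=a_ub, b_ub=b_ub,
                  bounds=[(None, None)] * points.shape[1], method="highs")
    return res.status == 0


@dataclass
class EmpiricalCapacity:
    fraction_separable: float       # at the probe (ambient) dimension
    capacity: float                 # P / n_star from bisection
    n_star: float                   # interpolated 50%-separable dimension


def empirical_capacity(ms: ManifoldSet, n_dichotomies: int = 25,
                       rng: np.random.Generator | int | None = 0
                       ) -> EmpiricalCapacity:
    """Monte-Carlo separability of random balanced manifold dichotomies.

    A dichotomy is separable when a single homogeneous hyperplane puts all
    member points of the +1 manifolds on one side and all points of the -1
    manifolds on the other.  The capacity estimate is P divided by the
    projection dimension at which half of random dichotomies separate
    (located by bisection over seeded Gaussian random projections, with
    linear interpolation between the bracketing dimensions).
    """
    if n_dichotomies < 1:
        raise ValueError("n_dichotomies must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    pts = [np.asarray(p, dtype=np.float64) for p in ms.points]
    stacked = np.concatenate(pts)
    owner = np.concatenate([np.full(p.shape[0], i)
                            for i, p in enumerate(pts)])
    p_count = ms.n_manifolds
    ambient = stacked.shape[1]
    dichotomies = [_balanced_dichotomy(p_count, rng)
                   for _ in range(n_dichotomies)]

    def fraction_at(dim: int) -> float:
        hits = 0
        for signs in dichotomies:
            if dim < ambient:
                proj = rng.normal(size=(ambient, dim)) / np.sqrt(dim)
                x = stacked @ proj
            else:
                x = stacked
            hits += linearly_separable(x, signs[owner.astype(int)])
        return hits / len(dichotomies)

    frac_ambient = fraction_at(ambient)
    if frac_ambient < 0.5:
        return EmpiricalCapacity(fraction_separable=frac_ambient,
                                 capacity=p_count / ambient,
                                 n_star=float(ambient))
    lo, f_lo = 1, fraction_at(1)
    if f_lo >= 0.5:
        return EmpiricalCapacity(fraction_separable=frac_ambient,
                                 capacity=float(p_count), n_star=1.0)
    hi, f_hi = ambient, frac_ambient
    while hi - lo > 1:
        mid = (lo + hi) // 2
        f_mid = fraction_at(mid)
        if f_mid >= 0.5:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    if f_hi == f_lo:
        n_star = float(hi)
    else:
        n_star = lo + (0.5 - f_lo) / (f_hi - f_lo) * (hi - lo)
    return EmpiricalCapacity(fraction_separable=frac_ambient,
                             capacity=p_count / n_star, n_star=n_star)


def center_correlation(ms: ManifoldSet) -> float:
    """Mean absolute pairwise Pearson correlation between manifold centers
    (alignment magnitude; self-pairs excluded)."""
    if ms.n_manifolds < 2:
        raise ValueError("need at least 2 manifolds")
    centers = ms.centers()
    centered = centers - centers.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    if valid.sum() < 2:
        return float("nan")
    c = centered[valid] / norms[valid, None]
    corr = np.abs(np.clip(c @ c.T, -1.0, 1.0))
    iu = np.triu_indices(valid.sum(), k=1)
    return float(corr[iu].mean())
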