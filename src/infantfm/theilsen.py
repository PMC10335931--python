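"""Theil-Sen robust linear regression, univariate and multivariate.

Univariate: the classical estimator — slope is the median of all pairwise
slopes, intercept the median of ``y - slope*x``. Exact over all pairs
whenever they are enumerable (bounded by ``max_pairs``), otherwise over a
seeded random sample of pairs.

Multivariate: the classical estimator has no unique generalization; here
the fit is the spatial median (geometric median, Weiszfeld iteration) of
exact least-squares solutions on random subsets of p+1 observations
(p covariates plus intercept), the same construction used by
``sklearn.linear_model.TheilSenRegressor``. All subsets are enumerated
when their number does not exceed ``max_subsets`` (default 10000);
otherwise that many are drawn at random, seeded. Breakdown: the estimate
tolerates a fraction of gross outliers roughly up to the point where
contaminated subsets form the majority — about ``1 - 0.5**(1/(p+1))`` of
the data — which shrinks as the number of covariates grows.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import comb
from scipy.stats import theilslopes

from .cohort import Visit
from .linmodel import LinearFMModel

__all__ = ["theil_sen_fit", "spatial_median", "RankDeficientError"]


class RankDeficientError(ValueError):
    """The design matrix is rank-deficient (collinear columns)."""


def spatial_median(
    points: np.ndarray, tol: float = 1e-12, max_iter: int = 500
) -> np.ndarray:
    """Geometric median of row vectors by Weiszfeld iteration.

    The point minimizing the sum of Euclidean distances to the rows.
    Iterates from the coordinate-wise median; a current estimate that
    coincides with a data point is perturbed per Vardi & Zhang.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        return np.array([np.median(pts)])
    x = np.median(pts, axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - x, axis=1)
        at_point = d < 1e-15
        if at_point.all():
            return x
        if at_point.any():
            d = np.where(at_point, np.inf, d)
        w = 1.0 / d
        x_new = (w[:, None] * pts).sum(axis=0) / w.sum()
        if at_point.any():
            # Vardi-Zhang step: pull toward the coincident data point
            # proportionally to how many rows sit exactly there.
            r = np.linalg.norm((w[:, None] * (pts - x)).sum(axis=0))
            eta = at_point.sum()
            if r > 0:
                x_new = max(0.0, 1.0 - eta / r) * x_new + min(1.0, eta / r) * x
            else:
                return x
        if np.linalg.norm(x_new - x) <= tol * (1.0 + np.linalg.norm(x)):
            return x_new
        x = x_new
    return x


def _check_rank(X: np.ndarray, variables: Optional[Sequence[str]]) -> None:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via pivoted QR on the design
        from scipy.linalg import qr

        _, _, piv = qr(design, pivoting=True, mode="economic")
        bad = sorted(piv[rank:])
        names = []
        for j in bad:
            if j == 0:
                names.append("(intercept)")
            elif variables is not None:
                names.append(variables[j - 1])
            else:
                names.append(f"column {j - 1}")
        raise RankDeficientError(
            f"design matrix is rank-deficient; collinear column(s): {names}"
        )


def _univariate(x: np.ndarray, y: np.ndarray):
    # scipy's estimator: slope = median of pairwise slopes over all pairs
    # with distinct x; method='joint' gives intercept = median(y - slope*x).
    res = theilslopes(y, x, method="joint")
    return float(res.intercept), np.array([float(res.slope)])


def _multivariate(
    X: np.ndarray,
    y: np.ndarray,
    max_subsets: int,
    rng: np.random.Generator,
):
    n, p = X.shape
    k = p + 1  # subset size: one observation per unknown (incl. intercept)
    # solve each square subset system in standardized coordinates — the LS
    # solution is the same point, but raw anthropometric columns (large
    # means, strong collinearity) make the raw systems too ill-conditioned
    # to detect genuinely singular subsets (e.g. all-one-sex draws)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    design = np.column_stack([np.ones(n), (X - mu) / sd])
    total = comb(n, k, exact=True)
    if total <= max_subsets:
        subsets = np.array(list(combinations(range(n), k)))
    else:
        subsets = np.empty((max_subsets, k), dtype=int)
        for i in range(max_subsets):
            subsets[i] = rng.choice(n, size=k, replace=False)
    A = design[subsets]  # (S, k, k), entries O(1)
    b = y[subsets]  # (S, k)
    dets = np.abs(np.linalg.det(A))
    hadamard = np.prod(np.linalg.norm(A, axis=2), axis=1)
    ok = np.isfinite(dets) & (dets > np.finfo(float).eps * k * hadamard)
    if not ok.any():
        raise RankDeficientError("every sampled subset was singular")
    sols = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
    sols = sols[np.all(np.isfinite(sols), axis=1)]
    if len(sols) == 0:
        raise RankDeficientError("no subset yielded a finite least-squares solution")
    # back-transform each subset solution to the raw scale before taking
    # the spatial median, so the estimator is defined on raw coefficients
    coefs_std = sols[:, 1:]
    betas = coefs_std / sd
    intercepts = sols[:, 0] - betas @ mu
    center = spatial_median(np.column_stack([intercepts, betas]))
    return float(center[0]), center[1:]


def theil_sen_fit(
    X,
    y,
    variables: Optional[Sequence[str]] = None,
    visit: Union[Visit, str, None] = None,
    max_pairs: int = 100000,
    max_subsets: int = 10000,
    seed: int = 0,
) -> LinearFMModel:
    """Robust linear fit of fat mass on covariates.

    Parameters
    ----------
    X : (n, p) array or CohortTable column matrix
        Covariates, one column per variable.
    y : (n,) array
        Measured fat mass, kg.
    variables : sequence of str, optional
        Column names (used for the returned model and error messages).
    visit : Visit, optional
        Visit tag for the returned model; defaults to 1M placeholder when
        not supplied by the caller.
    max_pairs, max_subsets : int
        Enumeration caps for the univariate / multivariate paths.
    seed : int
        Seed for subset sampling above the caps.

    Returns
    -------
    LinearFMModel
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in Theil-Sen input")
    if n < p + 2:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    if variables is None:
        variables = tuple(f"x{j}" for j in range(p))
    variables = tuple(variables)
    if len(variables) != p:
        raise ValueError(f"{p} columns but {len(variables)} variable names")
    _check_rank(X, variables)

    if p == 1:
        npairs = n * (n - 1) // 2
        if npairs > max_pairs:
            rng = np.random.default_rng(seed)
            keep = rng.choice(n, size=int(np.sqrt(2 * max_pairs)) + 1, replace=False)
            intercept, coefs = _univariate(X[keep, 0], y[keep])
        else:
            intercept, coefs = _univariate(X[:, 0], y)
    else:
        rng = np.random.default_rng(seed)
        intercept, coefs = _multivariate(X, y, max_subsets, rng)

    return LinearFMModel(
        visit=Visit.coerce(visit) if visit is not None else Visit.M1,
        variables=variables,
        coefficients=tuple(coefs),
        intercept=intercept,
        provenance=f"theil-sen fit (n={n}, p={p}, seed={seed})",
    )
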