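"""Variable selection by repeated LASSO with nonzero-coefficient voting.

The selection stage draws, many times over, a quintile-stratified 80%
subsample of the cohort (quintiles of measured fat mass, so every
subsample spans the outcome range), fits an L1-penalized linear model on
it, and records each candidate variable's coefficient. Over the default
100 blocks x 12 repetitions this yields 1200 coefficients per variable;
a variable is *selected* when it is nonzero in at least 500 of them.

The penalty for each repetition is chosen on that repetition's subsample
(5-fold cross-validation by default), which is what makes the individual
fits variable enough for vote counting to be informative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "CANDIDATE_VARIABLES",
    "SelectionSpec",
    "VoteTable",
    "quintile_bins",
    "stratified_subsample",
    "lasso_fit",
    "choose_lambda",
    "run_selection",
    "select_variables",
]

#: Default candidate set: sex, gestational age, weight, length, the five
#: circumferences and six skinfolds, plus BMI (the final equations use BMI,
#: so it joins the directly measured candidates).
CANDIDATE_VARIABLES = (
    "sex",
    "gestational_age_birth",
    "weight",
    "length",
    "bmi",
    "head_circ",
    "muac",
    "waist_circ",
    "thigh_circ",
    "calf_circ",
    "biceps_sf",
    "triceps_sf",
    "subscapular_sf",
    "waist_sf",
    "thigh_sf",
    "calf_sf",
)


@dataclass
class SelectionSpec:
    """Tuning of the repeated-LASSO vote count.

    ``blocks * reps_per_block`` is the total number of repetitions (default
    1200). ``vote_threshold`` is the minimum number of nonzero coefficients
    for a variable to be selected (default 500). ``lambda_rule`` is one of
    ``"cv"`` (per-repetition 5-fold cross-validated penalty, default),
    ``"lambda_1se"`` (largest penalty within one SE of the CV optimum), or
    ``"fixed"`` (use ``lambda_value`` everywhere).
    """

    blocks: int = 100
    reps_per_block: int = 12
    subsample_fraction: float = 0.80
    vote_threshold: int = 500
    n_quintiles: int = 5
    lambda_rule: str = "cv"
    lambda_value: Optional[float] = None
    n_lambdas: int = 30
    cv_folds: int = 5
    zero_tolerance: float = 1e-10
    candidates: Sequence[str] = CANDIDATE_VARIABLES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError(
                f"subsample_fraction must be in (0, 1], got {self.subsample_fraction}"
            )
        if self.blocks < 1 or self.reps_per_block < 1:
            raise ValueError("blocks and reps_per_block must be >= 1")
        if self.vote_threshold > self.blocks * self.reps_per_block:
            raise ValueError(
                f"vote_threshold {self.vote_threshold} exceeds total repetitions "
                f"{self.blocks * self.reps_per_block}"
            )
        if self.lambda_rule not in ("cv", "lambda_1se", "fixed"):
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.lambda_rule == "fixed" and self.lambda_value is None:
            raise ValueError("lambda_rule='fixed' requires lambda_value")
        self.candidates = tuple(self.candidates)

    @property
    def total_reps(self) -> int:
        return self.blocks * self.reps_per_block


@dataclass
class VoteTable:
    """All repetition coefficients and per-variable nonzero counts."""

    variables: tuple[str, ...]
    betas: np.ndarray  # (total_reps, n_variables), original scale
    zero_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 2 or self.betas.shape[1] != len(self.variables):
            raise ValueError(
                f"betas must be (reps, {len(self.variables)}), got {self.betas.shape}"
            )

    @property
    def total_reps(self) -> int:
        return self.betas.shape[0]

    @property
    def votes(self) -> dict[str, int]:
        counts = (np.abs(self.betas) > self.zero_tolerance).sum(axis=0)
        return {v: int(c) for v, c in zip(self.variables, counts)}

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "votes": self.votes,
            "total_reps": self.total_reps,
            "zero_tolerance": self.zero_tolerance,
            "betas": self.betas.tolist(),
        }

    @classmethod
    def from_dict(cls, data) -> "VoteTable":
        return cls(
            tuple(data["variables"]),
            np.asarray(data["betas"], dtype=float),
            float(data.get("zero_tolerance", 1e-10)),
        )


def quintile_bins(y: np.ndarray, k: int = 5) -> np.ndarray:
    """Assign each record to one of `k` contiguous rank bins of `y`.

    Records are ranked by value (ties broken by original order, stable)
    and cut into k groups whose sizes differ by at most one; when n is not
    a multiple of k the extra records go to the lowest-rank bins.

    Returns an integer bin index (0 = lowest values) per record.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    order = np.argsort(y, kind="stable")
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes):
        bins[order[start : start + size]] = b
        start += size
    return bins


def stratified_subsample(
    bins: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw round(fraction * size) indices (at least 1) from each bin.

    Sampling is without replacement within each bin; the union over bins
    is returned sorted for reproducibility.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    bins = np.asarray(bins)
    chosen = []
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        take = max(1, round(fraction * len(members)))
        chosen.append(rng.choice(members, size=min(take, len(members)), replace=False))
    return np.sort(np.concatenate(chosen))


def _path(Xs: np.ndarray, yc: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Coefficient path for standardized X / centered y; (p, n_alphas).

    Thin wrapper over the coordinate-descent path with the Gram matrix
    precomputed and input checks skipped (the callers guarantee float64,
    finite, properly-shaped input), which matters here because the
    selection stage calls this thousands of times.
    """
    Xf = np.asfortranarray(Xs, dtype=np.float64)
    yc = np.ascontiguousarray(yc, dtype=np.float64)
    gram = Xs.T @ Xs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(
            Xf, yc, alphas=alphas, precompute=gram, Xy=Xs.T @ yc, check_input=False
        )
    return coefs


def _standardize(X: np.ndarray):
    """Center/scale columns to mean 0, SD 1 (population SD); flag constants."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd_safe, constant


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float):
    """L1-penalized least squares: minimize ½·MSE + lam·Σ|β|.

    Predictors are standardized to mean 0 / SD 1 internally; the returned
    coefficients are back-transformed to the original scale, preserving
    exact zeros. The intercept is unpenalized. Constant columns are
    dropped (coefficient 0) with a warning.

    Returns ``(intercept, betas)`` with one beta per column of X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in LASSO input")
    Xs, mu, sd, constant = _standardize(X)
    if constant.any():
        logger.warning("dropping %d constant column(s) from LASSO fit", constant.sum())
        Xs[:, constant] = 0.0
    ym = y.mean()
    coefs = _path(Xs, y - ym, np.array([float(lam)]))
    beta_std = coefs[:, 0]
    beta_std[constant] = 0.0
    betas = beta_std / sd
    betas[constant] = 0.0
    intercept = ym - float(mu @ betas)
    return intercept, betas


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, n_lambdas: int, eps: float = 1e-3):
    lam_max = np.max(np.abs(Xs.T @ yc)) / len(yc)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def choose_lambda(
    X: np.ndarray, y: np.ndarray, spec: SelectionSpec
) -> float:
    """Pick the LASSO penalty for one repetition per ``spec.lambda_rule``.

    ``"cv"``: minimize k-fold cross-validated MSE over a geometric grid.
    ``"lambda_1se"``: largest penalty whose CV MSE is within one standard
    error of the minimum (fewer variables, same rule family as glmnet).
    ``"fixed"``: return ``spec.lambda_value`` unchanged.
    """
    if spec.lambda_rule == "fixed":
        return float(spec.lambda_value)
    Xs, _, _, constant = _standardize(np.asarray(X, dtype=float))
    Xs[:, constant] = 0.0
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    lambdas = _lambda_grid(Xs, yc, spec.n_lambdas)
    n = len(yc)
    folds = np.array_split(np.arange(n), spec.cv_folds)
    sq_err = np.zeros((spec.cv_folds, len(lambdas)))
    for k, test in enumerate(folds):
        train = np.concatenate([folds[j] for j in range(spec.cv_folds) if j != k])
        # re-center within the training block: the path fits no intercept
        x_center = Xs[train].mean(axis=0)
        y_center = yc[train].mean()
        coefs = _path(Xs[train] - x_center, yc[train] - y_center, lambdas)
        pred = (Xs[test] - x_center) @ coefs + y_center
        sq_err[k] = ((yc[test][:, None] - pred) ** 2).mean(axis=0)
    mean_mse = sq_err.mean(axis=0)
    best = int(np.argmin(mean_mse))
    if spec.lambda_rule == "cv":
        return float(lambdas[best])
    se = sq_err.std(axis=0, ddof=1) / np.sqrt(spec.cv_folds)
    within = np.flatnonzero(mean_mse <= mean_mse[best] + se[best])
    # lambdas are sorted descending, so the first index within one SE is
    # the largest (most parsimonious) penalty.
    return float(lambdas[within[0]])


def run_selection(cohort: CohortTable, spec: SelectionSpec) -> VoteTable:
    """Repeat (stratified subsample -> penalty choice -> LASSO) and record betas.

    Each of ``spec.total_reps`` repetitions draws a fresh quintile-
    stratified subsample, chooses its own penalty, fits, and stores the
    original-scale coefficients. Deterministic given ``spec.seed``. A
    repetition whose fit fails is recorded as all zeros (it still counts
    toward the denominator) with a logged warning.
    """
    variables = tuple(spec.candidates)
    X = cohort.design_matrix(variables)
    y = cohort.fm_array()
    bins = quintile_bins(y, spec.n_quintiles)
    rng = np.random.default_rng(spec.seed)
    betas = np.zeros((spec.total_reps, len(variables)))
    for rep in range(spec.total_reps):
        idx = stratified_subsample(bins, spec.subsample_fraction, rng)
        Xr, yr = X[idx], y[idx]
        try:
            lam = choose_lambda(Xr, yr, spec)
            _, b = lasso_fit(Xr, yr, lam)
            betas[rep] = b
        except Exception as exc:  # noqa: BLE001 — a bad rep must not kill the run
            logger.warning("repetition %d failed (%s); recording zero betas", rep, exc)
    return VoteTable(variables, betas, spec.zero_tolerance)


def select_variables(votes: VoteTable, threshold: int = 500) -> list[str]:
    """Variables whose nonzero count meets `threshold`, in candidate order."""
    if threshold > votes.total_reps:
        raise ValueError(
            f"threshold {threshold} exceeds total repetitions {votes.total_reps}"
        )
    counts = votes.votes
    return [v for v in votes.variables if counts[v] >= threshold]
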