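"""Repeated stratified train/test evaluation with median-aggregated models.

Model behavior is evaluated over 12 "folds", each an independent
quintile-stratified random split of the cohort into 70% training and 30%
test data (12 disjoint 30% test sets cannot partition a cohort, so the
folds are repeated random splits rather than a partition). A partial
model is fitted on each fold's training data by Theil-Sen regression; the
final model takes, per variable (and for the intercept), the median of
the 12 partial coefficients — an aggregation that is symmetric in the
folds and robust to the occasional erratic partial fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import CohortTable
from .linmodel import LinearFMModel
from .selection import quintile_bins, stratified_subsample
from .theilsen import theil_sen_fit

__all__ = ["CVSpec", "CVResult", "cv_split", "run_cv", "aggregate_fold_models"]


@dataclass
class CVSpec:
    """Fold count, train fraction, and seeding of the evaluation stage."""

    folds: int = 12
    train_fraction: float = 0.70
    n_quintiles: int = 5
    max_subsets: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if not (0 < self.train_fraction < 1):
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


@dataclass
class CVResult:
    """Partial models, per-fold test predictions, and the aggregated model.

    ``fold_test_predictions`` holds each partial model's predictions on
    its own held-out test set (the fold-level diagnostic); the final
    model's held-out predictions are in ``final_test_predictions``.
    """

    fold_models: list[LinearFMModel]
    fold_test_predictions: list[tuple[np.ndarray, np.ndarray]]  # (predicted, measured)
    final_test_predictions: list[tuple[np.ndarray, np.ndarray]]
    final_model: LinearFMModel

    @property
    def pooled_predictions(self) -> tuple[np.ndarray, np.ndarray]:
        """Final-model (predicted, measured) pairs pooled over fold test sets."""
        pred = np.concatenate([p for p, _ in self.final_test_predictions])
        meas = np.concatenate([m for _, m in self.final_test_predictions])
        return pred, meas

    def out_of_fold_r2(self) -> float:
        """Squared Pearson correlation of the final model on held-out data.

        The final model's predictions on each fold's test records, pooled
        across folds. Because the final model is the median over all
        folds, this is a lightly optimistic but fold-symmetric measure of
        predictive association.
        """
        pred, meas = self.pooled_predictions
        r = np.corrcoef(pred, meas)[0, 1]
        return float(r * r)


def cv_split(
    cohort_or_y,
    folds: int = 12,
    train_fraction: float = 0.70,
    seed: int = 0,
    n_quintiles: int = 5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw `folds` independent stratified train/test splits.

    Each fold bins measured FM into quintiles and draws
    round(train_fraction * bin size) training records from every bin; the
    test set is the complement, so train and test are disjoint and
    together cover the cohort. Deterministic given `seed`.
    """
    if isinstance(cohort_or_y, CohortTable):
        y = cohort_or_y.fm_array()
    else:
        y = np.asarray(cohort_or_y, dtype=float)
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if not (0 < train_fraction < 1):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(y) < n_quintiles + 1:
        raise ValueError(
            f"cohort of {len(y)} records is too small for {n_quintiles}-bin stratification"
        )
    bins = quintile_bins(y, n_quintiles)
    rng = np.random.default_rng(seed)
    splits = []
    all_idx = np.arange(len(y))
    for _ in range(folds):
        train = stratified_subsample(bins, train_fraction, rng)
        test = np.setdiff1d(all_idx, train)
        if len(test) == 0:
            raise ValueError("train fraction leaves an empty test set")
        splits.append((train, test))
    return splits


def aggregate_fold_models(
    fold_models: Sequence[LinearFMModel], provenance: str = ""
) -> LinearFMModel:
    """Per-coefficient median of partial models (intercept included).

    With an even number of folds the median is the mean of the two middle
    order statistics. Symmetric in fold order by construction.
    """
    if not fold_models:
        raise ValueError("no fold models to aggregate")
    variables = fold_models[0].variables
    for m in fold_models[1:]:
        if m.variables != variables:
            raise ValueError("fold models disagree on variables")
    coef_matrix = np.array([m.coefficients for m in fold_models])
    intercepts = np.array([m.intercept for m in fold_models])
    return LinearFMModel(
        visit=fold_models[0].visit,
        variables=variables,
        coefficients=tuple(np.median(coef_matrix, axis=0)),
        intercept=float(np.median(intercepts)),
        provenance=provenance or f"median of {len(fold_models)} partial models",
    )


def run_cv(
    cohort: CohortTable,
    variables: Sequence[str],
    spec: Optional[CVSpec] = None,
) -> CVResult:
    """Fit a partial Theil-Sen model per fold and aggregate by median.

    Every fold trains on its stratified 70% and predicts its held-out 30%;
    those test predictions are kept for out-of-fold diagnostics. A fold
    whose fit fails aborts the run — with only 12 folds, silently dropping
    one would bias the median. Deterministic given ``spec.seed``.
    """
    spec = spec or CVSpec()
    variables = tuple(variables)
    if not variables:
        raise ValueError("no variables selected: cannot train a model")
    X = cohort.design_matrix(variables)
    y = cohort.fm_array()
    splits = cv_split(
        y, spec.folds, spec.train_fraction, spec.seed, spec.n_quintiles
    )
    # independent per-fold seeds derived from the stage seed
    fold_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.folds) % (2**31)
    fold_models: list[LinearFMModel] = []
    fold_preds: list[tuple[np.ndarray, np.ndarray]] = []
    for f, (train, test) in enumerate(splits):
        model = theil_sen_fit(
            X[train],
            y[train],
            variables=variables,
            visit=cohort.visit,
            max_subsets=spec.max_subsets,
            seed=int(fold_seeds[f]),
        )
        pred = model.intercept + X[test] @ np.asarray(model.coefficients)
        fold_models.append(model)
        fold_preds.append((pred, y[test]))
    final = aggregate_fold_models(
        fold_models,
        provenance=(
            f"median of {spec.folds} Theil-Sen partial models "
            f"(visit={cohort.visit.value}, n={len(cohort)}, seed={spec.seed})"
        ),
    )
    final_coefs = np.asarray(final.coefficients)
    final_preds = [
        (final.intercept + X[test] @ final_coefs, y[test]) for _, test in splits
    ]
    return CVResult(fold_models, fold_preds, final_preds, final)
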