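"""High-level modelling interface: FatMassModel.fit() -> FatMassResults.

This is the front door of the package. A :class:`FatMassModel` is built
from a cohort (a :class:`~infantfm.cohort.CohortTable`, a DataFrame in the
standard schema, or a CSV path) and `fit()` runs the full development
procedure — low-%FM exclusion, repeated-LASSO vote-counting selection,
and 12-fold Theil-Sen training with median aggregation — returning a
:class:`FatMassResults` that carries the vote table, the partial and
final models, out-of-fold diagnostics, and a text ``summary()``.

>>> from infantfm import FatMassModel
>>> from infantfm.synthetic import GeneratorSpec, generate_cohort
>>> cohort = generate_cohort(GeneratorSpec("3M", seed=7))
>>> res = FatMassModel(cohort).fit(seed=7)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import io
import tempfile
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agreement import AgreementReport, validate_model
from .cohort import CohortTable, Visit, exclude_low_fm, load_cohort
from .crossval import CVResult, CVSpec, run_cv
from .linmodel import LinearFMModel, VARIABLE_SYMBOLS
from .selection import (
    CANDIDATE_VARIABLES,
    SelectionSpec,
    VoteTable,
    run_selection,
    select_variables,
)

__all__ = ["FatMassModel", "FatMassResults"]


class FatMassModel:
    """Fat-mass prediction-equation development for one visit cohort.

    Parameters
    ----------
    cohort : CohortTable
        Records with measured reference FM.
    candidates : sequence of str, optional
        Candidate variables offered to selection (default: sex,
        gestational age, weight, length, BMI, circumferences, skinfolds).
    fm_exclusion_pct : float
        Records below this %FM are excluded before development (default 5).
    """

    def __init__(
        self,
        cohort: CohortTable,
        candidates: Sequence[str] = CANDIDATE_VARIABLES,
        fm_exclusion_pct: float = 5.0,
    ) -> None:
        self.raw_cohort = cohort
        self.candidates = tuple(candidates)
        self.cohort, self.n_excluded = exclude_low_fm(cohort, fm_exclusion_pct)
        if len(self.cohort) == 0:
            raise ValueError("no records remain after the low-%FM exclusion")

    @classmethod
    def from_csv(cls, path: Union[str, Path], visit: Union[Visit, str], **kwargs) -> "FatMassModel":
        return cls(load_cohort(path, visit), **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, visit: Union[Visit, str], **kwargs
    ) -> "FatMassModel":
        """Build from a DataFrame in the standard cohort CSV schema."""
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            df.to_csv(fh, index=False)
            tmp = fh.name
        try:
            cohort = load_cohort(tmp, visit)
        finally:
            Path(tmp).unlink(missing_ok=True)
        return cls(cohort, **kwargs)

    def fit(
        self,
        selection: Optional[SelectionSpec] = None,
        cv: Optional[CVSpec] = None,
        seed: Optional[int] = None,
    ) -> "FatMassResults":
        """Run selection then cross-validated training.

        `seed`, when given, overrides the seeds of both stage specs
        (deriving independent child seeds for each stage).
        """
        selection = selection or SelectionSpec(candidates=self.candidates)
        cv = cv or CVSpec()
        if seed is not None:
            child = np.random.SeedSequence(seed).generate_state(2) % (2**31)
            selection.seed, cv.seed = int(child[0]), int(child[1])
        votes = run_selection(self.cohort, selection)
        selected = select_variables(votes, selection.vote_threshold)
        if not selected:
            raise ValueError(
                f"no variables reached the vote threshold "
                f"({selection.vote_threshold}/{selection.total_reps}); "
                "lower the threshold or revisit the candidate set"
            )
        cv_result = run_cv(self.cohort, selected, cv)
        return FatMassResults(self, selection, cv, votes, selected, cv_result)


class FatMassResults:
    """Results of one full equation-development run.

    Attributes
    ----------
    vote_table : VoteTable
        All repetition coefficients and nonzero vote counts.
    selected : list of str
        Variables that met the vote threshold, in candidate order.
    cv_result : CVResult
        Partial models, out-of-fold predictions, and the final model.
    final_model : LinearFMModel
        The median-aggregated equation.
    """

    def __init__(
        self,
        model: FatMassModel,
        selection_spec: SelectionSpec,
        cv_spec: CVSpec,
        vote_table: VoteTable,
        selected: list[str],
        cv_result: CVResult,
    ) -> None:
        self.model = model
        self.selection_spec = selection_spec
        self.cv_spec = cv_spec
        self.vote_table = vote_table
        self.selected = selected
        self.cv_result = cv_result

    @property
    def final_model(self) -> LinearFMModel:
        return self.cv_result.final_model

    @property
    def visit(self) -> Visit:
        return self.model.cohort.visit

    def predict(self, cohort: CohortTable) -> np.ndarray:
        return self.final_model.predict(cohort)

    def out_of_fold_r2(self) -> float:
        return self.cv_result.out_of_fold_r2()

    def validate(
        self, cohort: Optional[CohortTable] = None, **kwargs
    ) -> AgreementReport:
        """Agreement of the final model on `cohort` (default: training cohort)."""
        return validate_model(self.final_model, cohort or self.model.cohort, **kwargs)

    def coefficient_table(self) -> pd.DataFrame:
        """Per-variable votes and fold-coefficient spread for selected variables."""
        votes = self.vote_table.votes
        rows = []
        coef_matrix = np.array([m.coefficients for m in self.cv_result.fold_models])
        for j, name in enumerate(self.final_model.variables):
            fold_coefs = coef_matrix[:, j]
            rows.append(
                {
                    "variable": name,
                    "symbol": VARIABLE_SYMBOLS.get(name, name),
                    "votes": votes.get(name, np.nan),
                    "coef_median": self.final_model.coefficients[j],
                    "coef_fold_min": fold_coefs.min(),
                    "coef_fold_max": fold_coefs.max(),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable development summary."""
        buf = io.StringIO()
        cohort = self.model.cohort
        w = buf.write
        w("Fat-mass prediction equation development\n")
        w("=" * 56 + "\n")
        w(f"Visit:                {self.visit.value}\n")
        w(f"Records used:         {len(cohort)}")
        if self.model.n_excluded:
            w(f"  (after excluding {self.model.n_excluded} with %FM < 5)")
        w("\n")
        w(
            f"Selection:            {self.selection_spec.blocks} blocks x "
            f"{self.selection_spec.reps_per_block} reps, vote threshold "
            f"{self.selection_spec.vote_threshold}/{self.selection_spec.total_reps}\n"
        )
        w(
            f"Training:             {self.cv_spec.folds}-fold Theil-Sen, "
            f"{self.cv_spec.train_fraction:.0%} train per fold, median aggregation\n"
        )
        w(f"Out-of-fold R^2:      {self.out_of_fold_r2():.3f}\n\n")
        w("Vote counts (all candidates)\n")
        w("-" * 56 + "\n")
        votes = self.vote_table.votes
        for name in self.vote_table.variables:
            mark = "*" if name in self.selected else " "
            w(f"  {mark} {name:<24s} {votes[name]:>5d}\n")
        w("  (* selected)\n\n")
        w("Final model (median of partial betas)\n")
        w("-" * 56 + "\n")
        table = self.coefficient_table()
        for _, row in table.iterrows():
            w(
                f"  {row['variable']:<24s} {row['coef_median']:>10.4f}   "
                f"fold range [{row['coef_fold_min']:.4f}, {row['coef_fold_max']:.4f}]\n"
            )
        w(f"  {'intercept':<24s} {self.final_model.intercept:>10.4f}\n\n")
        w(self.final_model.equation_string() + "\n")
        return buf.getvalue()
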