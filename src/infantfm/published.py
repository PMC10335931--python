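"""The three published fat-mass prediction equations, frozen as shipped.

These are the final age-specific equations derived from the Mexican OBESO
perinatal cohort (healthy term infants, air-displacement plethysmography
reference), with coefficients stored exactly at their printed 3-decimal
precision. They are never re-derived here; models retrained by this
package live in separate files and never overwrite this set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable, Visit
from .linmodel import LinearFMModel

__all__ = ["PUBLISHED_EQUATIONS", "published_equation", "score_batch"]


def _eq(visit: str, coefs: dict[str, float], intercept: float) -> LinearFMModel:
    return LinearFMModel.from_mapping(
        visit, coefs, intercept, provenance=f"published equation, {visit} visit"
    )


#: Published equations keyed by visit. Coefficient order follows the
#: printed equations (circumferences, BMI, skinfolds, gestational age).
PUBLISHED_EQUATIONS: dict[Visit, LinearFMModel] = {
    Visit.M1: _eq(
        "1M",
        {
            "thigh_circ": 0.068,
            "bmi": 0.018,
            "waist_sf": 0.026,
            "thigh_sf": 0.010,
            "subscapular_sf": 0.009,
        },
        -1.082,
    ),
    Visit.M3: _eq(
        "3M",
        {
            "waist_circ": 0.006,
            "thigh_circ": 0.074,
            "calf_circ": 0.078,
            "bmi": 0.062,
            "calf_sf": 0.024,
            "subscapular_sf": 0.054,
            "triceps_sf": -0.062,
            "gestational_age_birth": -0.053,
        },
        -1.045,
    ),
    Visit.M6: _eq(
        "6M",
        {
            "thigh_circ": 0.030,
            "calf_circ": 0.163,
            "waist_sf": 0.023,
            "thigh_sf": 0.034,
            "subscapular_sf": 0.019,
            "gestational_age_birth": -0.050,
        },
        -0.858,
    ),
}


def published_equation(visit) -> LinearFMModel:
    """The published equation for `visit` (1M, 3M, or 6M)."""
    return PUBLISHED_EQUATIONS[Visit.coerce(visit)]


def score_batch(
    cohort: CohortTable,
    visit=None,
    model: LinearFMModel | None = None,
    pct_low: float = 5.0,
    pct_high: float = 40.0,
) -> pd.DataFrame:
    """Score every record with the visit's published equation (or `model`).

    Returns a DataFrame with ``infant_id``, ``predicted_fm_kg``,
    ``predicted_fm_pct`` (of body weight) and ``qc_flags``. Implausible
    predictions (negative FM, %FM outside [`pct_low`, `pct_high`]) are
    flagged, never dropped: the thresholds are quality-control aids, not
    exclusions.
    """
    if model is None:
        if visit is None:
            visit = cohort.visit
        model = published_equation(visit)
    if Visit.coerce(model.visit) is not cohort.visit:
        raise ValueError(
            f"model is for visit {model.visit.value}, cohort is {cohort.visit.value}"
        )
    # per-record evaluation (not a vectorized dot product) so batch scores
    # agree bit-for-bit with single-record prediction
    pred = np.array([model.predict_record(rec) for rec in cohort])
    weights = np.array([rec.weight for rec in cohort])
    pct = 100.0 * pred / weights
    flags = []
    for p, q in zip(pred, pct):
        f = []
        if p < 0:
            f.append("negative_fm")
        if q < pct_low:
            f.append(f"pct_below_{pct_low:g}")
        elif q > pct_high:
            f.append(f"pct_above_{pct_high:g}")
        flags.append(";".join(f))
    return pd.DataFrame(
        {
            "infant_id": [rec.infant_id for rec in cohort],
            "predicted_fm_kg": pred,
            "predicted_fm_pct": pct,
            "qc_flags": flags,
        }
    )
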