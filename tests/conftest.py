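"""Shared fixtures: small synthetic cohorts and record builders."""

from __future__ import annotations

import numpy as np
import pytest

from infantfm.cohort import CohortTable, InfantRecord, exclude_low_fm
from infantfm.synthetic import GeneratorSpec, generate_cohort


def make_record(infant_id="a", visit="3M", sex="female", fm_kg=1.2, **overrides):
    """A valid 3-month record with plausible defaults, overridable per field."""
    base = dict(
        infant_id=infant_id,
        visit=visit,
        sex=sex,
        gestational_age_birth=39.0,
        age_days=93.0,
        weight=5.93,
        length=59.17,
        head_circ=39.93,
        muac=13.12,
        waist_circ=39.28,
        thigh_circ=21.41,
        calf_circ=15.81,
        biceps_sf=4.81,
        triceps_sf=8.51,
        subscapular_sf=8.16,
        waist_sf=8.00,
        thigh_sf=14.90,
        calf_sf=12.66,
        fm_kg=fm_kg,
    )
    base.update(overrides)
    return InfantRecord(**base)


@pytest.fixture
def record_builder():
    return make_record


@pytest.fixture(scope="session")
def cohort_3m():
    """Default-condition synthetic 3-month cohort (n=105), filtered."""
    spec = GeneratorSpec("3M", seed=314)
    cohort, _ = exclude_low_fm(generate_cohort(spec))
    return cohort


@pytest.fixture(scope="session")
def noiseless_6m():
    """Noise-free 6-month cohort whose FM is exactly the true linear model."""
    spec = GeneratorSpec("6M", n=300, noise_sd=0.0, low_fm_fraction=0.0, seed=27)
    return generate_cohort(spec), spec.true_model


@pytest.fixture(scope="session")
def big_3m():
    """Large 3-month draw for moment / calibration checks."""
    spec = GeneratorSpec("3M", n=10000, seed=99)
    return generate_cohort(spec), spec
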