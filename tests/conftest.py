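"""Shared fixtures: simulated cohorts reused across test modules."""

import warnings

import numpy as np
import pytest

from perimob.pipeline import analyze_cohort
from perimob.preprocess import NormalizedActivitySeries
from perimob.simulate import CohortConfig


@pytest.fixture(scope="session")
def low_noise_cohort():
    """500 patients under favourable recovery conditions, truth labels."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(
            500, CohortConfig.low_noise(), seed=101, label_source="truth"
        )


@pytest.fixture(scope="session")
def noise_free_cohort():
    """100 deterministic trajectories with exact generative boundaries."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(100, CohortConfig.noise_free(), seed=202)


def make_step_series(day_index, values, baseline_mean=5000.0, baseline_sd=3000.0,
                     patient_id="T0", smoothing_window=14):
    """Hand-crafted normalized series for boundary-condition tests."""
    return NormalizedActivitySeries(
        patient_id=patient_id,
        day_index=np.asarray(day_index, dtype=int),
        values=np.asarray(values, dtype=float),
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        smoothing_window=smoothing_window,
    )
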