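"""Shared fixtures: a session-scoped calibrated study run and small configs."""

from __future__ import annotations

import numpy as np
import pytest

from metabotrace import (
    CohortDesign,
    GeneratorConfig,
    MeasureSpec,
    run_calibrated_study,
)


@pytest.fixture(scope="session")
def calibrated_result():
    """Full pipeline on the calibrated synthetic study (published sizes).

    Shared across acceptance tests; reduced bootstrap/permutation counts
    keep it in the tens of seconds.
    """
    return run_calibrated_study(seed=1, n_boot=200, n_perm=299)


@pytest.fixture(scope="session")
def calibrated_truth(calibrated_result):
    """Hidden generative subgroup per projected subject."""
    yfs = calibrated_result.cohorts["yfs"]
    per_subject = yfs.drop_duplicates("subject_id").set_index("subject_id")
    return per_subject.loc[calibrated_result.labels.index, "true_subgroup"]


def two_axis_config(
    n_subjects: int = 400,
    visit_offsets=(0.0, 6.0, 10.0),
    baseline_age_range=(24.0, 24.0),
    seed: int = 0,
    noise_sd: float = 1.0,
    subject_sd: float = 1.0,
    extra_measures=(),
) -> GeneratorConfig:
    """Small two-axis study: one divergence and one progression measure."""
    measures = [
        MeasureSpec("div", loading_axis1=1.0),
        MeasureSpec("prog", loading_axis2=1.0),
        *extra_measures,
    ]
    return GeneratorConfig(
        cohort_designs=[
            CohortDesign("main", n_subjects, baseline_age_range, visit_offsets)
        ],
        measures=measures,
        axis1_intercepts=(0.0, 0.0, 0.0, 0.0),
        axis1_slopes=(0.5, -0.4, 0.1, 0.0),
        axis2_intercepts=(0.8, -0.8, 0.3, -0.3),
        axis2_slopes=(0.4, 0.4, 0.4, 0.4),
        subject_axis_sd=0.1,
        subject_random_intercept_sd=subject_sd,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
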