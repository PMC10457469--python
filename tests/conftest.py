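"""Shared fixtures: featurized synthetic cohorts at test scale."""

import numpy as np
import pytest

from eegage.pipeline import _synthetic_stream, featurize_cohort
from eegage.synthetic import CohortSpec, GeneratorTruth, generate_patient


@pytest.fixture(scope="session")
def default_truth():
    return GeneratorTruth()


@pytest.fixture(scope="session")
def ds1_table(default_truth):
    """Reference-group analogue: 170 propofol / ASA 1-2 patients, 600-s
    recordings, fixed seed."""
    spec = CohortSpec(
        n_patients=170, duration_s=600.0, seed=170,
        prop_propofol=1.0, prop_asa12=1.0,
    )
    table, _qc = featurize_cohort(_synthetic_stream(spec, default_truth))
    return table


@pytest.fixture(scope="session")
def small_table(default_truth):
    """Small mixed-drug cohort for fast model-behaviour tests."""
    spec = CohortSpec(
        n_patients=44, duration_s=300.0, seed=7,
        prop_propofol=0.5, prop_asa12=1.0,
    )
    table, _qc = featurize_cohort(_synthetic_stream(spec, default_truth))
    return table


@pytest.fixture(scope="session")
def clean_record(default_truth):
    """One artifact-free, suppression-free 600-s recording + its truth."""
    spec = CohortSpec(n_patients=1, duration_s=600.0, seed=99, prop_propofol=1.0)
    rec, pt = generate_patient(spec, default_truth, 0, with_bs=False, with_artifacts=False)
    return rec, pt
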