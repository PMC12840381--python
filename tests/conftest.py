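"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from lvscreen.features import extract_cohort
from lvscreen.synth import CohortConfig, SubjectProfile, generate_study


def covariate_frame(profiles):
    return pd.DataFrame([{
        "subject_id": p.subject_id, "sex": p.sex, "age": p.age,
        "smoking": p.smoking, "diabetes": p.diabetes,
        "hypertension": p.hypertension, "lvef": p.lvef,
    } for p in profiles])


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless, zero-HRV study conditions for exact delineation checks."""
    return CohortConfig(n_subjects=1, hr_mean_bpm=60.0, sdnn_target_ms=0.0,
                        noise_rms_uv=0.0, duration_s=60.0, seed=7)


@pytest.fixture(scope="session")
def fixed_profile():
    return SubjectProfile(subject_id="S0000", sex="male", age=60.0,
                          smoking=False, diabetes=False, hypertension=True,
                          lvef=62.0)


@pytest.fixture(scope="session")
def small_study():
    """120 subjects, short records, with noise: the workhorse cohort."""
    cfg = CohortConfig(n_subjects=120, duration_s=20.0, seed=123)
    profiles, records = generate_study(cfg)
    return cfg, profiles, records


@pytest.fixture(scope="session")
def small_features(small_study):
    cfg, profiles, records = small_study
    table = extract_cohort(records, covariate_frame(profiles), seed=cfg.seed)
    return table


@pytest.fixture(scope="session")
def noiseless_cohort():
    """200 noiseless records with ground truth, for recovery checks."""
    cfg = CohortConfig(n_subjects=200, duration_s=20.0, noise_rms_uv=0.0,
                       seed=42)
    profiles, records = generate_study(cfg)
    table = extract_cohort(records, covariate_frame(profiles), seed=cfg.seed)
    return profiles, records, table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
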