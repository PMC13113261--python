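import numpy as np
import pandas as pd
import pytest

import facesym as fs


@pytest.fixture(scope="session")
def dense_registry():
    return fs.load_registry("dense-225")


@pytest.fixture(scope="session")
def template(dense_registry):
    return fs.make_template(dense_registry)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort (seed 1): 60 patients x 9 expressions."""
    cfg = fs.SyntheticConfig(rng_seed=1)
    records, grades, truth = fs.generate_cohort(cfg)
    grades_df = pd.DataFrame([g.__dict__ for g in grades])
    return records, grades_df, truth


@pytest.fixture(scope="session")
def default_angles(default_cohort, dense_registry):
    records, grades_df, truth = default_cohort
    return fs.angle_table(records, dense_registry)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort with every stochastic deformation switched off."""
    cfg = fs.SyntheticConfig(
        n_patients=8,
        rng_seed=3,
        landmark_noise_sd=0.0,
        patient_effect_sd=0.0,
        baseline_asym_sd=0.0,
        head_tilt_range=(0.0, 0.0),
    )
    records, grades, truth = fs.generate_cohort(cfg)
    grades_df = pd.DataFrame([g.__dict__ for g in grades])
    return records, grades_df, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
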