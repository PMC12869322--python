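import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fcselect import ClinicalSimConfig, gen_clinical_dataset
from fcselect.fc_core import FCDataset, ROIRun, synthetic_pairs

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_clinical():
    """A small mixed-covariate cohort with a planted disorder component."""
    cfg = ClinicalSimConfig(
        n_control=60, n_patient=60, n_features=200, disorder_effect=0.8,
        n_disorder_fcs=12, n_sites=3, site_bias_sd=0.1, site_scale_sd=0.05,
        age_effect=0.05, sex_effect=0.05, seed=101,
    )
    return gen_clinical_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noisy_run(rng):
    signal = rng.standard_normal((80, 5))
    fd = np.concatenate([[0.0], np.abs(rng.normal(0.15, 0.1, 79))])
    return ROIRun(signal=signal, tr_seconds=2.0, fd=fd)


def make_dataset(values, subject_prefix="s"):
    values = np.asarray(values, dtype=float)
    ids = np.array([f"{subject_prefix}{k}" for k in range(values.shape[0])])
    return FCDataset(values, synthetic_pairs(values.shape[1]), ids)


@pytest.fixture()
def make_fc_dataset():
    return make_dataset
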