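import numpy as np
import pytest

import ttnorm as tn


@pytest.fixture(scope="session")
def pub_model():
    return tn.published_model()


@pytest.fixture(scope="session")
def sd_default():
    return tn.default_sd_profile()


@pytest.fixture(scope="session")
def pooled_seed0():
    """Harmonized synthetic pooled dataset at the study conditions.

    Thirteen study profiles (n = 10,360 before censoring), truth = the
    published mean curve, constant sigma = 0.15 on the log-adjusted scale,
    seed 0.  Shared across tests that exercise the full pipeline.
    """
    truth = tn.GroundTruth(sd_profile=0.15, seed=0)
    raw = tn.generate_dataset(tn.default_study_profiles(), truth)
    return tn.harmonize(raw)


@pytest.fixture(scope="session")
def uniform_noisy():
    """Single-study dataset, uniform-ish ages 3-88, sigma = 0.15, n = 2,000."""
    rng = np.random.default_rng(42)
    model = tn.published_model()
    ages = rng.uniform(3.0, 88.0, 2000)
    y = rng.normal(model.evaluate(ages), 0.15)
    tt = np.clip(tn.inverse_log_adjust(y), 0.0, None)
    from ttnorm.harmonize import make_dataset

    return make_dataset(ages, tt)
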