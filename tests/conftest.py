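import numpy as np
import pandas as pd
import pytest

from strataclock.io import BetaMatrix, SampleMeta
from strataclock.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 3-cohort simulation with every CpG class represented."""
    config = SimConfig(
        n_samples_per_cohort=100,
        n_cohorts=3,
        seed=11,
        class_counts={
            "linear": 30,
            "logistic": 20,
            "piecewise_phase": 40,
            "sex_modulated": 20,
            "null": 90,
        },
        noise_sd=0.3,
    )
    return simulate_cohort(config)


@pytest.fixture
def toy_beta():
    return BetaMatrix(
        probe_ids=["cg01", "cg02", "cg03"],
        sample_ids=["s1", "s2"],
        values=np.array([[0.1, 0.2], [0.5, np.nan], [0.9, 1.0]]),
    )


@pytest.fixture
def toy_meta():
    return SampleMeta(
        sample_id=["s1", "s2"],
        age=np.array([25.0, 60.0]),
        sex=np.array([0, 1]),
        cohort=["a", "b"],
    )
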