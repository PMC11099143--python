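import warnings

import numpy as np
import pandas as pd
import pytest

from patmodels import (
    CardiacParams,
    TaskConfig,
    build_schedule,
    reference_params,
    simulate_analysis_table,
)

warnings.filterwarnings("ignore", message="subject .*constant regressor")


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def one_subject_schedule(task_config):
    return build_schedule(task_config, n_subjects=1, seed=11)


@pytest.fixture(scope="session")
def noiseless_cardiac():
    return CardiacParams(
        baseline_bpm_mean=60.0,
        baseline_bpm_sd=0.0,
        decel_mean=-2.0,
        decel_subject_sd=0.0,
        decel_trial_sd=0.0,
        beat_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_base_table():
    """20 subjects x 150 balanced long trials generated from the base model."""
    return simulate_analysis_table(reference_params("base"), n_subjects=20, n_runs=3, seed=101)


@pytest.fixture
def feature_frame():
    """Hand-built standardized feature rows for direct DV evaluation."""

    def make(z_money=0.0, z_shocks=0.0, z_dms=0.0, z_dhr=0.0, ac_code=1.0, n=1):
        return pd.DataFrame(
            {
                "z_money": np.full(n, z_money),
                "z_shocks": np.full(n, z_shocks),
                "z_dms": np.full(n, z_dms),
                "z_dhr": np.full(n, z_dhr),
                "ac_code": np.full(n, ac_code),
            }
        )

    return make
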