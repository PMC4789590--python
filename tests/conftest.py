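import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methclock import MethylationMatrix, SimulationConfig, make_cohort_pair

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def beta_matrix(probe_ids, columns):
    """Build a MethylationMatrix from {sample: [beta per probe]} mapping."""
    return MethylationMatrix(pd.DataFrame(columns, index=pd.Index(probe_ids)))


@pytest.fixture(scope="session")
def three_cpg_ids():
    return ["cg02228185", "cg25809905", "cg17861230"]


@pytest.fixture(scope="session")
def small_cohort_pair():
    """Deterministic train/test cohorts with shared probe truth."""
    train_cfg = SimulationConfig(
        n_samples=300, n_age_cpgs=10, n_null_cpgs=5, noise_sd=0.01,
        acceleration_sd=0.0, seed=101,
    )
    test_cfg = train_cfg.replace(
        n_samples=600, acceleration_sd=5.0, log_hr_per_5yr=np.log(1.5), seed=202
    )
    return make_cohort_pair(train_cfg, test_cfg)


def rename_probes(matrix: MethylationMatrix, prefix: str) -> MethylationMatrix:
    values = matrix.values.copy()
    values.index = pd.Index([f"{prefix}{p}" for p in values.index])
    return MethylationMatrix(values)


def stack_matrices(*matrices: MethylationMatrix) -> MethylationMatrix:
    return MethylationMatrix(pd.concat([m.values for m in matrices], axis=0))
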