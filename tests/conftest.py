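import numpy as np
import pytest

from copdsim import load_parameters
from copdsim.cohort import Cohort


@pytest.fixture(scope="session")
def params():
    return load_parameters("defaults")


def make_cohort(n, *, sex=0, age=60.0, has_copd=False, fev1_pct=1.0,
                diagnosed=False, treatment=-1, params=None):
    """Hand-built homogeneous cohort for unit tests."""
    stage = 0
    if has_copd:
        from copdsim.natural_history import gold_stage
        stage = gold_stage(fev1_pct)
    c = Cohort(
        id=np.arange(n, dtype=np.int64),
        sex=np.full(n, sex, dtype=np.int8),
        age=np.full(n, float(age)),
        has_copd=np.full(n, bool(has_copd)),
        fev1_pct=np.full(n, float(fev1_pct)),
        stage=np.full(n, stage, dtype=np.int8),
        diagnosed=np.full(n, bool(diagnosed)),
        treatment=np.full(n, treatment, dtype=np.int8),
        months_since_exac=np.full(n, np.inf),
        months_on_treatment=np.zeros(n),
        care_stage=np.where(np.full(n, bool(diagnosed)), stage, -1).astype(np.int8),
        ever_screened=np.zeros(n, dtype=bool),
        alive=np.ones(n, dtype=bool),
        death_cause=np.zeros(n, dtype=np.int8),
        creation_seed=0,
        parameters_hash=params.digest() if params is not None else "",
    )
    return c
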