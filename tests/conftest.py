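import numpy as np
import pandas as pd
import pytest

from stratakit.data_model import create_study
from stratakit.pipeline import RunConfig, run_pipeline
from stratakit.synthetic import SyntheticSpec, generate


@pytest.fixture
def mixed_table() -> pd.DataFrame:
    """Small table with numeric, binary and categorical columns."""
    rng = np.random.default_rng(7)
    n = 12
    return pd.DataFrame(
        {
            "age": rng.normal(60, 8, n).round(1),
            "bmi": rng.normal(27, 3, n).round(1),
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "stage": rng.choice(["I", "II", "III"], n),
        },
        index=[f"P{i}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def small_run():
    """One complete small pipeline run shared by interpretation tests."""
    spec = SyntheticSpec(n=100, k_true=2, blocks=[(4, 0.8, 4.0), (4, 0.8, 4.0)], seed=3)
    raw, truth, _ = generate(spec)
    study, _ = create_study(raw, labels=truth)
    result = run_pipeline(study, None, RunConfig(n_boot=12, seed=3))
    return study, truth, result
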