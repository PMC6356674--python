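import numpy as np
import pandas as pd
import pytest

from vitdmr import SimConfig, add_scores, simulate_cohort
from vitdmr.io_harmonize import validate_participants


@pytest.fixture(scope="session")
def sim_table() -> pd.DataFrame:
    """A mid-sized synthetic three-cohort sample with scores attached."""
    table = simulate_cohort(SimConfig(seed=20240717).scaled(6000))
    return add_scores(validate_participants(table))


def make_participants(n: int = 5, seed: int = 0, **overrides) -> pd.DataFrame:
    """Small hand-adjustable, valid participant table."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "cohort": ["AGES"] * n,
            "age": rng.normal(67, 10, n).round(1),
            "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
            "season": [("spring", "summer", "fall", "winter")[i % 4] for i in range(n)],
            "bmi": rng.normal(27, 4, n).round(1),
            "smoker": rng.binomial(1, 0.2, n),
            "diabetes": rng.binomial(1, 0.1, n),
            "hypertension": rng.binomial(1, 0.7, n),
            "cvd_history": rng.binomial(1, 0.2, n),
            "cancer_history": rng.binomial(1, 0.1, n),
            "x25ohd": rng.normal(52, 18, n).clip(1).round(1),
            "followup": rng.uniform(1, 15, n).round(2),
            "death": rng.binomial(1, 0.4, n),
            "rs12794714": rng.binomial(2, 0.4, n),
            "rs10741657": rng.binomial(2, 0.4, n),
            "rs12785878": rng.binomial(2, 0.4, n),
            "rs11234027": rng.binomial(2, 0.4, n),
        }
    )
    for key, value in overrides.items():
        df[key] = value
    return df
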