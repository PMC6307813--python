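import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from adsexnet import CohortMetadata, ExpressionMatrix
from adsexnet.simulate import default_config, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_expr() -> ExpressionMatrix:
    """6 genes x 8 samples with fixed values; g1 == 2*g2 (perfectly correlated)."""
    rng = np.random.default_rng(42)
    base = rng.uniform(10, 100, size=(6, 8))
    base[1] = 2.0 * base[0]
    return ExpressionMatrix(
        pd.DataFrame(
            base,
            index=[f"g{i}" for i in range(1, 7)],
            columns=[f"s{i}" for i in range(1, 9)],
        )
    )


@pytest.fixture()
def tiny_meta(tiny_expr) -> CohortMetadata:
    df = pd.DataFrame(
        {
            "sample_id": tiny_expr.sample_ids,
            "subject_id": [f"p{i}" for i in range(8)],
            "sex": ["male"] * 4 + ["female"] * 4,
            "region": ["frontal pole"] * 4 + ["putamen"] * 4,
            "stage": ["normal", "possible_AD", "probable_AD", "definite_AD"] * 2,
            "braak_score": [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5],
        }
    ).set_index("sample_id")
    return CohortMetadata(df)


@pytest.fixture(scope="session")
def demo_cohort():
    """One default synthetic cohort shared across tests (seed 1)."""
    return simulate_cohort(default_config(seed=1))
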