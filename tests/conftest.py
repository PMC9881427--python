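import numpy as np
import pandas as pd
import pytest

from oralsim import SyntheticConfig, generate_brushing_data
from oralsim.environment import UserBaseModel, build_environment


@pytest.fixture(scope="session")
def default_records() -> pd.DataFrame:
    """One default-shaped synthetic dataset (32 users x 28 days x 2)."""
    return generate_brushing_data(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_records() -> pd.DataFrame:
    """A small dataset (8 users) for fast environment builds."""
    return generate_brushing_data(SyntheticConfig(n_users=8, seed=11))


@pytest.fixture(scope="session")
def small_env(small_records):
    return build_environment(small_records, "S_Pop", seed=5)


def make_model(
    model_class="hurdle_sqrt",
    w_b=(0.4, 0.0, 0.0, 0.0),
    w_n=(10.0, 0.0, 0.0, 0.0),
    sigma_n=1.0,
    user_id=0,
    base="stationary",
    study_length=28,
    rmse=0.0,
) -> UserBaseModel:
    """Hand-built user model for oracle tests."""
    if model_class == "zip":
        sigma_n = None
    return UserBaseModel(
        user_id=user_id,
        model_class=model_class,
        w_b=np.asarray(w_b, dtype=float),
        w_n=np.asarray(w_n, dtype=float),
        sigma_n=sigma_n,
        rmse=rmse,
        base=base,
        study_length=study_length,
    )
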