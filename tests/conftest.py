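import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from admin_prev import SynthConfig, generate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A compact but fully featured study: ~90 true cases in 100k persons."""
    return SynthConfig(population_size=100_000, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_profiles() -> pd.DataFrame:
    """Hand-built person profiles covering the capture patterns."""
    rows = [
        # id, n_h, n_d, n_o, resident
        (1, 1, 1, 1, True),
        (2, 2, 0, 0, True),
        (3, 0, 1, 0, True),
        (4, 0, 0, 3, True),
        (5, 1, 2, 0, False),
    ]
    df = pd.DataFrame(
        rows, columns=["person_id", "n_hospital", "n_drug", "n_outpatient",
                       "resident"]
    )
    df["n_records_total"] = df[["n_hospital", "n_drug", "n_outpatient"]].sum(
        axis=1
    )
    for s in ("hospital", "drug", "outpatient"):
        df[f"cap_{s}"] = (df[f"n_{s}"] >= 1).astype(int)
    df["sex"] = ["F", "M", "F", "F", "M"]
    df["birth_year"] = [1980, 1975, 1990, 1963, 1988]
    df["area"] = ["AV", "SA", "NA1", "NA2", "CE"]
    return df
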