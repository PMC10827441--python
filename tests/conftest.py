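import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from caninecancer.io_datasets import BreedRecord, DatasetTable
from caninecancer.lifespan import DEFAULT_LIFESPAN
from caninecancer.synthetic_data import SyntheticConfig, generate_panel


@pytest.fixture
def lifespan_model():
    return DEFAULT_LIFESPAN


@pytest.fixture
def small_table():
    """Three hand-written breeds with valid fields."""
    return DatasetTable(
        source_id="tiny",
        records=[
            BreedRecord("Alpha", 5.0, 0.10, n_deaths=100),
            BreedRecord("Bravo", 25.0, 0.30, n_deaths=200),
            BreedRecord("Charlie", 45.0, 0.40, n_deaths=150),
        ],
    )


@pytest.fixture
def noiseless_m4_table(lifespan_model):
    """Mortalities generated exactly from A4 = 7.84e-7 with no noise."""
    rng = np.random.default_rng(42)
    w = np.sort(rng.uniform(2, 60, size=40))
    t = lifespan_model.predict(w)
    p = 7.84e-7 * w * t**4
    return DatasetTable(
        source_id="noiseless",
        records=[
            BreedRecord(f"b{i}", float(wi), float(pi)) for i, (wi, pi) in enumerate(zip(w, p))
        ],
    )


@pytest.fixture
def default_panel():
    """One synthetic panel at the study-default configuration."""
    return generate_panel(SyntheticConfig(seed=1))
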