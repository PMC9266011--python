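import numpy as np
import pytest

from gwrisk.core_data import METALS, ConcentrationTable
from gwrisk.synthetic import generate, three_source_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """3 sites × 7 metals with simple hand-checkable values."""
    values = np.array(
        [
            [5.0, 100.0, 30.0, 1.0, 20.0, 0.05, 2.0],
            [10.0, 200.0, 60.0, 2.0, 40.0, 0.10, 4.0],
            [15.0, 300.0, 90.0, 3.0, 60.0, 0.15, 6.0],
        ]
    )
    return ConcentrationTable(
        site_ids=["A", "B", "C"], metals=list(METALS), values=values
    )


@pytest.fixture
def random_table(rng):
    """60 × 7 lognormal table (no latent structure)."""
    values = rng.lognormal(mean=1.0, sigma=0.8, size=(60, 7))
    return ConcentrationTable(
        site_ids=[f"S{i}" for i in range(60)], metals=list(METALS), values=values
    )


@pytest.fixture(scope="session")
def benchmark_table():
    """One fixed draw of the 3-source benchmark generator, with truth."""
    table, truth = generate(three_source_spec(seed=11, noise_cv=0.1))
    return table, truth


def write_csv(tmp_path, text, name="table.csv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path
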