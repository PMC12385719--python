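import numpy as np
import pytest

import germeval as ge


@pytest.fixture(scope="session")
def panel259():
    """Default reference-calibrated 259-accession panel, seed 7."""
    table, truth = ge.generate(ge.default_config(seed=7))
    return table, truth


@pytest.fixture(scope="session")
def panel5000():
    """Large calibration panel (n=5000) from the default config, seed 1."""
    table, truth = ge.generate(ge.default_config(n_accessions=5000, seed=1))
    return table, truth


def make_table(n: int = 12, seed: int = 0, values: np.ndarray | None = None):
    """A small valid 34-trait table with cycling metadata levels."""
    rng = np.random.default_rng(seed)
    reg = ge.default_registry()
    if values is None:
        values = rng.uniform(10.0, 90.0, size=(n, len(reg)))
    origin = np.array([ge.ORIGIN_LEVELS[i % 6] for i in range(n)], dtype=object)
    period = np.array([ge.PERIOD_LEVELS[i % 4] for i in range(n)], dtype=object)
    ids = [f"A{i + 1:03d}" for i in range(n)]
    return ge.TraitTable(ids, origin, period, np.asarray(values, float), reg)


@pytest.fixture
def small_table():
    return make_table(n=12, seed=3)
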