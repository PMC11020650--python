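import numpy as np
import pytest

from dbdnmf.io_data import ResponseMatrix


def random_masked_matrix(rng, m=None, n=None, observed_fraction=0.7):
    """A random ResponseMatrix with at least one observed entry."""
    m = m or int(rng.integers(2, 8))
    n = n or int(rng.integers(2, 9))
    values = rng.standard_normal((m, n)) * rng.uniform(0.5, 3.0) + rng.uniform(-2, 2)
    mask = rng.random((m, n)) < observed_fraction
    if not mask.any():
        mask[0, 0] = True
    values = np.where(mask, values, np.nan)
    return ResponseMatrix(values=values, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rm(rng):
    return random_masked_matrix(rng, m=5, n=6)


@pytest.fixture
def toy_csv(tmp_path):
    """A 5x6 matrix CSV with a couple of missing cells, for CLI tests."""
    rng = np.random.default_rng(7)
    values = rng.standard_normal((5, 6)).round(4)
    values[1, 2] = np.nan
    values[4, 0] = np.nan
    rm = ResponseMatrix(values=values, unit_label="test")
    from dbdnmf.io_data import write_response_csv

    path = tmp_path / "toy.csv"
    write_response_csv(rm, str(path))
    return str(path)
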