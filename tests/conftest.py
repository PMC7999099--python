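import numpy as np
import pytest

from ospca import DataMatrix, SampleDesign, autoscale


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def one_group_design(n, order=None):
    order = list(range(n)) if order is None else order
    return SampleDesign(
        tuple(f"s{i}" for i in range(n)), tuple("A" for _ in range(n)), tuple(order)
    )


def random_autoscaled(rng, n, p):
    """Random Gaussian data, autoscaled (divisor-n convention)."""
    raw = DataMatrix(
        rng.normal(size=(n, p)),
        tuple(f"s{i}" for i in range(n)),
        tuple(f"m{j}" for j in range(p)),
    )
    return autoscale(raw)


@pytest.fixture
def small_design():
    """Two groups of three ordered samples."""
    return SampleDesign(
        tuple(f"s{i}" for i in range(6)),
        ("A", "A", "A", "B", "B", "B"),
        (0.0, 1.0, 2.0, 0.0, 1.0, 2.0),
    )
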