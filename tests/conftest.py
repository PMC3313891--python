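import numpy as np
import pytest

from kmrecon.datasets import (
    load_example_curve,
    load_example_input,
    load_example_risk_table,
)


@pytest.fixture
def example_curve():
    """31 digitized coordinates of the radiotherapy-arm example (0-10 months)."""
    return load_example_curve()


@pytest.fixture
def example_risk():
    return load_example_risk_table()


@pytest.fixture
def example_input():
    return load_example_input()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def write_lines(path, rows, delimiter=","):
    with open(path, "w") as fh:
        for row in rows:
            fh.write(delimiter.join(str(v) for v in row) + "\n")
    return str(path)
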