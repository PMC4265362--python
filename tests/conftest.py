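import numpy as np
import pytest

from mstgsa import CountMatrix, PhenotypeLabels


@pytest.fixture
def tiny_cm() -> CountMatrix:
    counts = np.array([[3, 0], [1, 2]])
    return CountMatrix(["g1", "g2"], counts, ["s1", "s2"], [100, 200])


@pytest.fixture
def labels10() -> PhenotypeLabels:
    samples = [f"s{i}" for i in range(10)]
    return PhenotypeLabels(samples, ["A"] * 5 + ["B"] * 5, group_order=("A", "B"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140397)


def write_tsv(path, text):
    path.write_text(text)
    return str(path)
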