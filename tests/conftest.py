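import pytest

from qtcda import EvaluationGrid, default_pair, reference_table


@pytest.fixture(scope="session")
def table():
    """The packaged six-antipsychotic effect table (p0 = 0.5)."""
    return reference_table()


@pytest.fixture(scope="session")
def pair():
    """Default sigmoid utility pair: improved 30–100, unimproved 0–30, slope 0.05."""
    return default_pair()


@pytest.fixture(scope="session")
def grid():
    """Default baseline-QTc grid {420, 450, 480, 510} ms."""
    return EvaluationGrid()
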