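import numpy as np
import pytest

from ismkit.datasets import load_case_study
from ismkit.engine import ABSENT, DIRECT, ReachabilityMatrix


@pytest.fixture(scope="session")
def study():
    return load_case_study()


def make_rm(rows: list[list[int]], flavor: str = "initial") -> ReachabilityMatrix:
    """Build a matrix from 0/1 rows; codes 1..n; diagonal forced direct."""
    a = np.array(rows, dtype=np.int8)
    np.fill_diagonal(a, DIRECT)
    return ReachabilityMatrix(tuple(range(1, len(rows) + 1)), a, flavor=flavor)


def random_rm(rng: np.random.Generator, n: int, density: float = 0.3) -> ReachabilityMatrix:
    a = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(a, DIRECT)
    return ReachabilityMatrix(tuple(range(1, n + 1)), a, flavor="initial")
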