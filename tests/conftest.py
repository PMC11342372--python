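import numpy as np
import pytest

from banditea.structures import ToyCalculator, build_structure, parse_formula

C9H7N = parse_formula("C9H7N")


@pytest.fixture(scope="session")
def calc():
    return ToyCalculator()


@pytest.fixture(scope="session")
def builder_library():
    """12 random C9H7N builds (fixed seed), unrelaxed."""
    rng = np.random.default_rng(20240917)
    return [build_structure(C9H7N, rng=rng) for _ in range(12)]


@pytest.fixture(scope="session")
def relaxed_library(builder_library, calc):
    """The same builds, locally optimised with the toy calculator."""
    return [calc.relax(s, 100, 0.05) for s in builder_library]
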