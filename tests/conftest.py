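import numpy as np
import pytest

from pcombine import WeightedPValueSet

# five p-values whose weights agree to ~1e-5 — the canonical nearly
# degenerate input on which double-precision Good's formula collapses
NEARLY_EQUAL_PVALUES = (0.008000257, 0.008579261, 0.0008911761, 0.006967988, 0.004973110)
NEARLY_EQUAL_WEIGHTS = (0.54531152, 0.54532057, 0.54531221, 0.54531399, 0.54531776)


@pytest.fixture
def nearly_equal_set() -> WeightedPValueSet:
    return WeightedPValueSet(NEARLY_EQUAL_PVALUES, NEARLY_EQUAL_WEIGHTS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_valid_set(rng: np.random.Generator, L: int, distinct: bool = True) -> WeightedPValueSet:
    p = rng.uniform(1e-6, 1.0, size=L)
    if distinct:
        w = np.sort(rng.uniform(0.3, 3.0, size=L))
        while len(np.unique(w)) < L or np.any(np.diff(w) < 1e-3):
            w = np.sort(rng.uniform(0.3, 3.0, size=L))
    else:
        w = np.full(L, float(rng.uniform(0.3, 3.0)))
    return WeightedPValueSet(p.tolist(), w.tolist())
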