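import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from bnlattice.candidates import CandidateSets
from bnlattice.data import CATEGORICAL, CONTINUOUS, DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240307)


@pytest.fixture
def fig_candidates():
    """The 4-node worked-example candidate sets: pp1={2,4}, pp2={1,3},
    pp3={2}, pp4={1}."""
    names = ["v1", "v2", "v3", "v4"]
    pp = {
        "v1": {"v2", "v4"},
        "v2": {"v1", "v3"},
        "v3": {"v2"},
        "v4": {"v1"},
    }
    po = {v: {u for u in names if v in pp[u]} for v in names}
    return CandidateSets(pp=pp, po=po, feas_set=names, alpha=0.3)


@pytest.fixture
def chain_data(rng):
    """Strong chain x1 -> x2 -> x3, N = 1000."""
    n = 1000
    x1 = rng.standard_normal(n)
    x2 = 1.2 * x1 + rng.standard_normal(n)
    x3 = -1.0 * x2 + rng.standard_normal(n)
    return DataMatrix(
        pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}),
        kinds={c: CONTINUOUS for c in ("x1", "x2", "x3")},
    )


def make_categorical_data(rng, n=200):
    a = rng.integers(0, 2, size=n)
    b = (a + rng.integers(0, 2, size=n)) % 3
    c = rng.integers(0, 2, size=n)
    frame = pd.DataFrame({"a": a.astype(str), "b": b.astype(str), "c": c.astype(str)})
    return DataMatrix(frame, kinds={k: CATEGORICAL for k in "abc"})
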