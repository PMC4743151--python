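import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from causalbn import (
    CPT,
    CausalNetwork,
    StateSpace,
    Topology,
    make_sprinkler,
)

FIXTURES = Path(__file__).parent.parent / "src" / "causalbn" / "fixtures"


@pytest.fixture
def sprinkler() -> CausalNetwork:
    return make_sprinkler()


@pytest.fixture
def chain_xy() -> CausalNetwork:
    """X -> Y with P(X=1)=0.5, P(Y=1|X=0)=0.1, P(Y=1|X=1)=0.9."""
    return CausalNetwork(
        topology=Topology(["X", "Y"], [("X", "Y")]),
        states=StateSpace.from_cards({"X": 2, "Y": 2}),
        cpts={
            "X": CPT("X", (), np.array([0.5, 0.5])),
            "Y": CPT("Y", ("X",), np.array([[0.9, 0.1], [0.1, 0.9]])),
        },
    )


@pytest.fixture
def single_binary() -> CausalNetwork:
    """One binary node A with P(1)=0.25."""
    return CausalNetwork(
        topology=Topology(["A"]),
        states=StateSpace.from_cards({"A": 2}),
        cpts={"A": CPT("A", (), np.array([0.75, 0.25]))},
    )


@pytest.fixture
def em_missing_data() -> pd.DataFrame:
    """Single variable A observed [1, 1, 0, missing]."""
    return pd.DataFrame(
        [[1.0, 1.0, 0.0, np.nan]], index=["A"], columns=["s0", "s1", "s2", "s3"]
    )


@pytest.fixture
def fixtures_dir() -> Path:
    return FIXTURES
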