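"""Shared fixtures.  All data here is synthetic, generated from seeds."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from funvul import (
    CommunityState,
    FixtureSpec,
    RunConfig,
    TraitTable,
    generate_community,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def small_traits() -> TraitTable:
    """4 species, 2 continuous + 1 nominal trait, one missing value."""
    df = pd.DataFrame(
        {
            "size": [1.0, 2.0, 4.0, 3.0],
            "depth": [10.0, np.nan, 30.0, 20.0],
            "diet": ["fish", "plankton", "fish", "benthos"],
        },
        index=["a", "b", "c", "d"],
    )
    kinds = {"size": "continuous", "depth": "continuous", "diet": "nominal"}
    return TraitTable(df, kinds)


@pytest.fixture
def clustered_fixture():
    """S=12 community with 3 tight trait clusters and uneven abundances."""
    return generate_community(
        FixtureSpec(s=12, k=3, sigma=0.05, evenness=0.7, seed=3)
    )


def make_state(sizes, weights=None, mode="occurrence") -> CommunityState:
    """Community with given entity sizes; species ids are stable."""
    cells, w = [], []
    for e, m in enumerate(sizes):
        cells.extend([(0, e)] * m)
    s = len(cells)
    if weights is None:
        weights = np.ones(s) if mode == "occurrence" else np.arange(1.0, s + 1)
    ids = [f"sp{i:02d}" for i in range(s)]
    return CommunityState(ids, cells, np.asarray(weights, dtype=float), mode)


@pytest.fixture
def abundance_cfg() -> RunConfig:
    return RunConfig(mode="abundance", replicates=30, seed=7)
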