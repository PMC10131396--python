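import numpy as np
import pandas as pd
import pytest

from coralmeta import (
    ExpressionMatrix,
    cpm,
    generate_counts,
    generate_design,
)

SMALL_SIZES = {"coral": 60, "symbiodiniaceae": 50, "prokaryote": 50}


@pytest.fixture(scope="session")
def design4():
    return generate_design(4, seed=0)


@pytest.fixture(scope="session")
def small_dataset(design4):
    """Small tri-compartment count set with 10% planted DE per compartment."""
    return generate_counts(
        design4, n_transcripts=SMALL_SIZES, de_fraction=0.1, seed=11
    )


@pytest.fixture(scope="session")
def small_cpm(small_dataset):
    mats, _ = small_dataset
    return {comp: cpm(mat) for comp, mat in mats.items()}


@pytest.fixture()
def tiny_cpm():
    """Hand-sized CPM matrix for arithmetic checks."""
    data = pd.DataFrame(
        {
            "s1": [100.0, 300.0, 999600.0],
            "s2": [400.0, 100.0, 999500.0],
        },
        index=["t1", "t2", "t3"],
    )
    return ExpressionMatrix("coral", "cpm", data)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
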