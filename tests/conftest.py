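import numpy as np
import pandas as pd
import pytest

from islecomm.core_io import OccurrenceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_matrix():
    """3 species x 4 islands with one empty island and known pair betas."""
    return OccurrenceMatrix(pd.DataFrame(
        [[1, 1, 0, 0],
         [0, 1, 1, 0],
         [1, 0, 1, 0]],
        index=["s1", "s2", "s3"],
        columns=["i1", "i2", "i3", "i4"],
    ))


@pytest.fixture
def toy_taxa():
    return pd.DataFrame(
        {
            "family": ["FamA", "FamB", "FamA"],
            "division": ["moss", "liverwort", "moss"],
            "growth_form": ["acrocarpous", "not_applicable", "pleurocarpous"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="species_id"),
    )


@pytest.fixture
def random_matrix(rng):
    """Dense-ish random 10x15 incidence matrix without empty margins."""
    while True:
        cells = (rng.random((10, 15)) < 0.35).astype(int)
        if cells.sum(0).all() and cells.sum(1).all():
            break
    return OccurrenceMatrix(pd.DataFrame(
        cells,
        index=[f"s{i}" for i in range(10)],
        columns=[f"i{j}" for j in range(15)],
    ))
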