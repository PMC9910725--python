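import numpy as np
import pandas as pd
import pytest

from betafacets.io_tables import OccurrenceMatrix
from betafacets.synthetic_data import SynthConfig, generate_dataset
from betafacets.trait_space import TraitTable


@pytest.fixture(scope="session")
def default_dataset():
    """One study-like synthetic dataset (58 species x 20 basins), fixed seed."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture
def toy_occurrence():
    """3 basins x 4 species with hand-checkable pair counts."""
    return OccurrenceMatrix(
        scenario="historical",
        basins=["b1", "b2", "b3"],
        species=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1, 1, 0],
                [1, 0, 1],
                [0, 1, 1],
                [1, 1, 1],
            ]
        ),
    )


@pytest.fixture
def toy_traits():
    """Three species whose Gower distances are computable by hand."""
    data = pd.DataFrame(
        {
            "body_length": [10.0, 20.0, 30.0],
            "migration": [1, 3, 5],
            "diet": [2, 2, 4],
            "water_column": [1, 2, 2],
            "fecundity": [1, 1, 4],
        },
        index=pd.Index(["s1", "s2", "s3"], name="species_id"),
    )
    return TraitTable(species=["s1", "s2", "s3"], data=data.astype(float))
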