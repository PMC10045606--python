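import numpy as np
import pandas as pd
import pytest

from floodmeadow.io import CoverMatrix


@pytest.fixture
def small_cover() -> CoverMatrix:
    """Three plots × three species with known scores."""
    scores = pd.DataFrame(
        {
            "Carex acuta": [5, 1, 0],
            "Alopecurus pratensis": [0, 3, 4],
            "Ranunculus acris": [1, 1, 1],
        },
        index=[1, 2, 3],
    )
    scores.index.name = "plot_id"
    return CoverMatrix(survey_year=1982, scores=scores)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
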