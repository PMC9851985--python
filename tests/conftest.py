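import numpy as np
import pandas as pd
import pytest

from ataxiamap.cohort import Cohort
from ataxiamap.model import PopulationParams
from ataxiamap.scales import SARA, ScaleDefinition


@pytest.fixture
def toy_scale() -> ScaleDefinition:
    """Three-item scale small enough for hand computation."""
    return ScaleDefinition(
        name="toy", items=(("a", 2), ("b", 3), ("c", 2)), column_prefix="toy"
    )


@pytest.fixture
def toy_pop(toy_scale) -> PopulationParams:
    return PopulationParams.for_scale(
        toy_scale,
        deltas=[np.array([2.0]), np.array([1.5, 2.5]), np.array([3.0])],
        offsets=np.array([0.0, 1.0, 0.5]),
        steepness=np.array([0.5, 0.8, 0.6]),
        tau_pop=40.0,
        sigma_tau=5.0,
        sigma_xi=0.3,
    )


@pytest.fixture
def tiny_sara_cohort() -> Cohort:
    """Two subjects, four visits, hand-written SARA scores."""
    df = pd.DataFrame(
        {
            "subject_id": ["p1", "p1", "p1", "p2"],
            "age": [40.0, 41.0, 42.0, 55.5],
            "sara_1": [1, 2, 2, 5],
            "sara_2": [0, 1, 1, 4],
            "sara_3": [0, 0, 1, 2],
            "sara_4": [1, 1, 2, 3],
            "sara_5": [0, 0, 1, 2],
            "sara_6": [0, 1, 1, 2],
            "sara_7": [0, 0, 0, 3],
            "sara_8": [1, 1, 1, 2],
            "sca_type": ["SCA1"] * 3 + ["SCA3"],
            "sex": ["F"] * 3 + ["M"],
            "cag": [47, 47, 47, 70],
            "cohort": ["EUROSCA"] * 3 + ["SPATAX"],
            "continent": ["Europe"] * 4,
        }
    )
    return Cohort(df=df, scale=SARA)
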