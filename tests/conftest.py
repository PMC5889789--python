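import numpy as np
import pandas as pd
import pytest

from efsubtype import CohortSpec, generate_cohort
from efsubtype.preprocess import SCALES


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Synthetic cohort of 3 x 40 children with known group structure."""
    return generate_cohort(CohortSpec(n_per_group=40, seed=11))


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    from efsubtype import residualize_age

    return residualize_age(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_residual_frame(profiles: np.ndarray) -> pd.DataFrame:
    """Wrap a children-by-6 score matrix as a residual table."""
    frame = pd.DataFrame(profiles, columns=list(SCALES))
    frame.insert(0, "child_id", [f"c{i}" for i in range(len(profiles))])
    return frame
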