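import numpy as np
import pandas as pd
import pytest

from refeedomics import CohortDesign, simulate_cohort
from refeedomics.io import FeatureTable


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-arm cohort reused across read-only tests."""
    design = CohortDesign(
        n_subjects_per_arm=10,
        n_taxa=40,
        n_modules=10,
        n_immune=10,
        med_confounded_features=4,
        seed=42,
    )
    return simulate_cohort(design)


@pytest.fixture()
def toy_counts():
    data = pd.DataFrame(
        [[5, 3, 2], [10, 0, 10], [1, 1, 1]],
        index=["s1:V1", "s1:V2", "s2:V1"],
        columns=["taxA", "taxB", "taxC"],
    )
    return FeatureTable(data, space="taxa16S", unit="counts")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
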