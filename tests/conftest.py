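import numpy as np
import pandas as pd
import pytest

from oligopath.pso import PsoConfig
from oligopath.simulate import CohortSpec, PatchSpec, generate_feature_cohort, generate_patch


@pytest.fixture(scope="session")
def small_cohort():
    """Informative cohort used by several model-level tests."""
    table = generate_feature_cohort(
        CohortSpec(n_subjects=240, n_features=10, n_informative=4, effect_size=1.2, seed=5)
    )
    y = table["label"].to_numpy()
    X = table.drop(columns=["label"])
    return X, y


@pytest.fixture(scope="session")
def default_patch():
    return generate_patch(PatchSpec(class_label=0, seed=1))


@pytest.fixture
def fast_pso():
    def make(seed=0, bounds=((-5.0, 5.0), (-5.0, 5.0)), **kw):
        kw.setdefault("max_iter", 60)
        kw.setdefault("patience", None)
        return PsoConfig(bounds=bounds, seed=seed, **kw)

    return make


def make_normalized(X: pd.DataFrame) -> pd.DataFrame:
    lo, hi = X.min(), X.max()
    return ((X - lo) / (hi - lo)).clip(0, 1)
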