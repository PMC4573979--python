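import numpy as np
import pandas as pd
import pytest

from seropanel.preprocess import preprocess_scans
from seropanel.simulate import (
    CohortSpec,
    GroupSpec,
    PanelSpec,
    default_informative,
    generate_array_scans,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    spec = CohortSpec(
        groups=(GroupSpec("AIH", 15, 13 / 15), GroupSpec("HD", 78, 20 / 78)),
        phase="discovery",
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_panel() -> PanelSpec:
    return PanelSpec(
        n_antigens=120,
        informative=default_informative(8, 120, seed=5),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scans(small_cohort, small_panel) -> pd.DataFrame:
    return generate_array_scans(small_cohort, small_panel)


@pytest.fixture(scope="session")
def small_pre(small_scans, small_cohort):
    return preprocess_scans(small_scans, small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def planted_signal_data(
    n_pos: int = 15,
    n_neg: int = 24,
    p: int = 200,
    n_informative: int = 20,
    shift: float = 2.0,
    seed: int = 0,
):
    """Gaussian two-class data with a block of mean-shifted features."""
    g = np.random.default_rng(seed)
    X = g.standard_normal((n_pos + n_neg, p))
    X[:n_pos, :n_informative] += shift
    y = np.array(["AIH"] * n_pos + ["HD"] * n_neg)
    return X, y
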