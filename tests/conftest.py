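import numpy as np
import pandas as pd
import pytest

from granulosig.config import AnalysisConfig
from granulosig.io import ExpressionMatrix
from granulosig.simulate import study_config, simulate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """One study-condition cohort (reduced gene universe) shared across tests."""
    cfg = study_config(n_genes=4000, seed=2)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture()
def tiny_expr():
    """3 genes x 6 samples, 2 per group, hand-sized."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.lognormal(4, 0.3, size=(3, 6)),
        index=["G1", "G2", "G3"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture()
def tiny_samples():
    return pd.Series(
        ["presurgical", "presurgical", "SIRS", "SIRS", "sepsis", "sepsis"],
        index=[f"s{i}" for i in range(6)],
        name="group",
    )
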