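import numpy as np
import pandas as pd
import pytest

from stagenet import simdata
from stagenet.iohub import ExpressionMatrix, StageDesign


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    """Small study-design replica: 8 stages x 2 replicates, 5 planted
    stage-peaked modules."""
    return simdata.default_config(seed=1, n_genes=600, module_size=50)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_design(small_config) -> StageDesign:
    return small_config.design()


@pytest.fixture()
def random_expression() -> ExpressionMatrix:
    """30 genes x 16 samples of NB noise (no planted structure)."""
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(10, 10 / (10 + 50.0), size=(30, 16))
    design = StageDesign.balanced()
    df = pd.DataFrame(
        counts,
        index=[f"g{i:03d}" for i in range(30)],
        columns=design.sample_ids,
    )
    return ExpressionMatrix(df, kind="counts")
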