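import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cernet import ExpressionMatrix, PipelineConfig, SimulationSpec, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_spec() -> SimulationSpec:
    return SimulationSpec(
        n_mrna=40, n_lncrna=15, n_mirna=25, n_planted_triplets=5, rng_seed=11
    )


@pytest.fixture
def small_dataset(small_spec):
    return generate_dataset(small_spec)


def make_expr(
    rows: dict[str, list[float]],
    conditions: tuple[str, ...] = ("dry", "early", "peak"),
    n_replicates: int = 3,
    feature_class: str = "mRNA",
) -> ExpressionMatrix:
    """Matrix with *exact* condition means: every replicate equals the mean.

    ``rows`` maps feature id -> one value per condition.
    """
    design = [(c, f"r{i+1}") for c in conditions for i in range(n_replicates)]
    data = {
        fid: [m for m in means for _ in range(n_replicates)]
        for fid, means in rows.items()
    }
    df = pd.DataFrame.from_dict(data, orient="index", dtype=float)
    df.columns = [f"{c}_{r}" for c, r in design]
    return ExpressionMatrix(df, design, feature_class)


@pytest.fixture
def expr_factory():
    return make_expr
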