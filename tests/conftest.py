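import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from corewire.io import ExpressionMatrix, SampleDesign
from corewire.simulate import SimulationConfig, simulate_expression

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_matrix(values, feature_ids=None, sample_ids=None, kind="mRNA"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(m)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        feature_kind=kind)


def balanced_design(n_per_group=4, phenotypes=("HC", "ADU", "ADT", "ID")):
    return SampleDesign({f"{p}_{i}": p
                         for p in phenotypes for i in range(n_per_group)})


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=400, n_mirnas=40,
                            n_samples_per_phenotype={"HC": 12, "ADU": 12,
                                                     "ADT": 12, "ID": 12},
                            n_regulators_per_kind=3, n_decoys_per_kind=5,
                            targets_per_regulator=30, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_expression(small_config)
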