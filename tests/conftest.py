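from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from leukomet import (
    ExpressionMatrix,
    SimulationConfig,
    build_reference_panel,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def fitted_reference(default_config):
    """Default synthetic reference with fitted NSC model and k=25 panels."""
    return build_reference_panel(default_config, seed=11, k=25)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_924)


def make_matrix(values, gene_ids=None, sample_ids=None, labels=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), sample_labels=labels
    )
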