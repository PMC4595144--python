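"""Shared fixtures: small synthetic datasets and helpers."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexdiff.simulate import PlantedModule, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact dataset with one planted module, DE probes and QC defects."""
    cfg = SimulationConfig(
        n_cases=40, n_controls=40, n_probes=400,
        planted_modules=[PlantedModule(size=40, r_case=0.0, r_control=0.7)],
        n_de_genes=10, de_effect=1.5,
        n_duplicates=2, n_outliers=2, n_low_rin=2, seed=7,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def log2_expr(ds) -> pd.DataFrame:
    """Log2 view of a synthetic dataset's raw expression matrix."""
    return pd.DataFrame(np.log2(ds.expression.to_numpy(float)),
                        index=ds.expression.index,
                        columns=ds.expression.columns)
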