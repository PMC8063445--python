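import numpy as np
import pandas as pd
import pytest

from txrestore.io import ExpressionMatrix, StudyDesign
from txrestore.simulate import SimulationConfig, simulate_expression


@pytest.fixture
def small_dataset():
    """A modest noisy dataset with three treatments of increasing restoration."""
    config = SimulationConfig(
        n_genes=400,
        n_per_group=3,
        n_treatments=3,
        frac_disease_genes=0.1,
        effect_size_low=1.5,
        effect_size_high=3.0,
        restoration_fractions=[0.0, 0.5, 1.0],
        off_target_frac=0.0,
        noise_sd=0.25,
        seed=7,
    )
    return simulate_expression(config)


@pytest.fixture
def two_group_matrix():
    """A tiny deterministic two-group matrix for contrast unit tests."""
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.normal(8, 1, size=(30, 6)),
        index=[f"g{i:03d}" for i in range(30)],
        columns=["A1", "A2", "A3", "B1", "B2", "B3"],
    )
    matrix = ExpressionMatrix(data)
    design = StudyDesign(
        sample_to_group={s: s[0] for s in data.columns},
        baseline_group="B",
        disease_group="A",
    )
    return matrix, design
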