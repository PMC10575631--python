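import numpy as np
import pandas as pd
import pytest

from protprio import SimConfig, StudyDesign, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated experiment shared by read-only tests."""
    cfg = SimConfig(n_proteins=300, n_sets=40, set_size_range=(5, 20), seed=7)
    counts, design, truth = simulate_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture
def toy_design():
    samples = [f"h{i}" for i in range(1, 5)] + [f"p{i}" for i in range(1, 5)]
    return StudyDesign(
        conditions=pd.Series(["healthy"] * 4 + ["patient"] * 4, index=samples),
        contrasts=[("healthy", "patient")],
    )


@pytest.fixture
def toy_matrix(toy_design):
    rng = np.random.default_rng(0)
    vals = rng.poisson(12, size=(30, 8))
    return pd.DataFrame(
        vals,
        index=[f"P{i:03d}" for i in range(30)],
        columns=toy_design.samples,
    )
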