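import numpy as np
import pandas as pd
import pytest

from tilsig.io import ExpressionMatrix, z_normalize_rows
from tilsig.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic neoadjuvant cohort (n = 300, seed 1)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def normalized_default(default_cohort):
    return z_normalize_rows(default_cohort.expression)


@pytest.fixture
def small_matrix():
    """Deterministic 8×30 gene-keyed z-normalized matrix."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(8)]
    samples = [f"S{i}" for i in range(30)]
    frame = pd.DataFrame(rng.standard_normal((8, 30)), index=genes, columns=samples)
    return z_normalize_rows(ExpressionMatrix(frame))
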