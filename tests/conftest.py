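import numpy as np
import pandas as pd
import pytest

from spatialtma.config import PipelineConfig
from spatialtma.synth import SynthConfig, generate_cohort


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """4 cores x 600 cells with intensities; shared read-only fixture."""
    config = SynthConfig(n_cores=4, cells_per_core=600, seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def typed_cells(small_cohort):
    """Cell table with ground-truth types exposed as `cell_type` (bypasses
    clustering for stages downstream of phenotyping)."""
    cells, clinical, truth = small_cohort
    cells = cells.copy()
    cells["cell_type"] = cells["true_type"]
    cells["compartment"] = cells["true_compartment"]
    return cells, clinical, truth


def random_typed_sample(
    rng: np.random.Generator,
    n: int,
    types=("A", "B", "C", "D"),
    extent: float = 500.0,
    sample_id: str = "s0",
) -> pd.DataFrame:
    """Uniform random point pattern with uniformly drawn type labels."""
    return pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_{i}" for i in range(n)],
            "sample_id": sample_id,
            "x_um": rng.random(n) * extent,
            "y_um": rng.random(n) * extent,
            "cell_type": rng.choice(list(types), n),
        }
    )
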