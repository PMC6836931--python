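import numpy as np
import pandas as pd
import pytest

from retrodyn import simulate
from retrodyn.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default simulated study (seed 0)."""
    return run_pipeline(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated bundle for cheap structural tests."""
    design = simulate.SimulationDesign(
        n_transcripts=400,
        modules=(
            simulate.PlantedModule("M_transient", 30, "transient_45min", log2_effect=2.0),
            simulate.PlantedModule("M_up24h", 40, "up_24h", log2_effect=2.0),
            simulate.PlantedModule("M_down24h", 25, "down_24h", log2_effect=2.0),
        ),
        seed=5,
    )
    return simulate.simulate_study(design)


@pytest.fixture()
def toy_counts():
    """3 transcripts x 2 samples with hand-checkable size factors."""
    return pd.DataFrame(
        [[2, 4], [3, 6], [10, 20]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
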