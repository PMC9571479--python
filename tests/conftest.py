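import numpy as np
import pandas as pd
import pytest

from mirsig import CtMatrix, SampleSheet, SimulationConfig, simulate_cohort


def make_ct(values, assays=None, samples=None, spikeins=()):
    """Small CtMatrix builder for fixtures."""
    arr = np.asarray(values, dtype=float)
    assays = assays or [f"miR-{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return CtMatrix(pd.DataFrame(arr, index=assays, columns=samples), tuple(spikeins))


def make_sheet(groups, samples=None, cohort="discovery"):
    samples = samples or [f"S{i}" for i in range(len(groups))]
    return SampleSheet(
        pd.DataFrame(
            {"group": list(groups), "cohort": cohort},
            index=pd.Index(samples, name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def discovery_cohort():
    """Default discovery-style synthetic cohort (16 patients vs 22 controls)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-panel cohort for faster end-to-end tests."""
    return simulate_cohort(SimulationConfig(n_assays=120, seed=5))
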