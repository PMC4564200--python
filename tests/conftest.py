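import numpy as np
import pandas as pd
import pytest

from brockmet import simulate as sim
from brockmet.inference import records_to_frame


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (37 animals) as records + frame + truth."""
    records, truth = sim.simulate_cohort(sim.CohortSimConfig(seed=7))
    return records, records_to_frame(records), truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Cohort with zero residual noise: RMR is an exact linear function."""
    records, truth = sim.simulate_cohort(
        sim.CohortSimConfig(residual_sd=0.0, seed=11)
    )
    return records_to_frame(records), truth


@pytest.fixture()
def plateau_trace():
    """Hand-built trace: linear settling for 60 min then a flat plateau."""
    from brockmet.traces import GasTrace

    t = np.arange(0.0, 101.0, 2.0)
    o2 = np.where(t < 60, 0.2090 - (0.2090 - 0.2050) * t / 60.0, 0.2050)
    co2 = np.full_like(t, 0.0036)
    return GasTrace(time_min=t, fe_o2=o2, fe_co2=co2, flow_ml_min=46120.0)
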