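import numpy as np
import pandas as pd
import pytest

from immuscore import SimulationConfig, generate_cohort, write_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient default-parameter cohort shared across tests."""
    return generate_cohort(SimulationConfig(seed=11, n_patients=120))


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """The 200-patient demo cohort written to disk once per session."""
    directory = tmp_path_factory.mktemp("demo")
    cohort = generate_cohort(SimulationConfig(seed=7, n_patients=200))
    write_cohort(cohort, directory)
    return directory


@pytest.fixture()
def toy_survival():
    """Small tie-free survival frame with a binary group covariate."""
    rng = np.random.default_rng(42)
    n = 60
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(np.exp(-0.8 * x) * 12)
    c = rng.exponential(30, n)
    return pd.DataFrame(
        {
            "time_months": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "x": x,
        }
    )
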