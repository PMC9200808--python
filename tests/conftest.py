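import numpy as np
import pandas as pd
import pytest

import frcompare as fc


@pytest.fixture(scope="session")
def paper_design() -> fc.DesignSpec:
    return fc.default_design()


@pytest.fixture(scope="session")
def scenario() -> fc.ScenarioParams:
    return fc.default_scenario()


@pytest.fixture(scope="session")
def experiment_frame(paper_design, scenario) -> pd.DataFrame:
    """One full synthetic experiment (binomial generator, fixed seed)."""
    trials = fc.simulate_experiment(paper_design, scenario, "binomial", seed=2026)
    return fc.trials_to_frame(trials)


@pytest.fixture(scope="session")
def male_warm_group(experiment_frame) -> pd.DataFrame:
    df = experiment_frame
    return df[(df.sex == "M") & (df.temperature == 22.0) & (df.salinity == 15.0)]


def binomial_group(a, h, reps=5, densities=(1, 2, 4, 6, 8, 16, 32, 64), seed=0):
    """Kill counts for one treatment group under the fitting likelihood."""
    rng = np.random.default_rng(seed)
    n0 = np.tile(densities, reps).astype(float)
    p = np.clip(fc.rogers_expected_kills(n0, (a, h)) / n0, 0, 1)
    ne = rng.binomial(n0.astype(int), p)
    return n0, ne.astype(float)


def group_frame(n0, ne, sex="M", temperature=16.0, salinity=15.0):
    return pd.DataFrame(
        {"sex": sex, "temperature": temperature, "salinity": salinity,
         "n_initial": n0.astype(int), "n_killed": ne.astype(int),
         "duration": 1.0, "is_control": False}
    )
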