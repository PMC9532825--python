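import numpy as np
import pytest

from pfsim import ShutdownConfig, TrialDesign, scenario_1, scenario_2


@pytest.fixture(scope="session")
def design1() -> TrialDesign:
    return scenario_1()


@pytest.fixture(scope="session")
def design2() -> TrialDesign:
    return scenario_2()


@pytest.fixture()
def small_design() -> TrialDesign:
    """Fast design for structural tests: 80 patients, 50-event trigger."""
    return TrialDesign(
        n_patients=80,
        median_pfs_control=10.0,
        hazard_ratio=0.6,
        accrual_duration=6.0,
        target_events=50,
    )


@pytest.fixture()
def shutdown_12_18() -> ShutdownConfig:
    return ShutdownConfig(start=12.0, duration=6.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
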