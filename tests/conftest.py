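import numpy as np
import pytest

from mecgwas import DoseEvent, DosingHistory, PKParameters
from mecgwas.io import default_pk_parameters


@pytest.fixture(scope="session")
def one_comp() -> PKParameters:
    """One-compartment degeneracy: k12=k13=0 so only the k10 mode is dosed."""
    return PKParameters(v1=10.0, k10=0.1, k12=0.0, k21=0.05, k13=0.0, k31=0.01, ke0=0.5)


@pytest.fixture(scope="session")
def fentanyl() -> PKParameters:
    return default_pk_parameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def bolus_history() -> DosingHistory:
    return DosingHistory("s1", [DoseEvent(0.0, 100.0, "initial_bolus")], 600.0)


def random_params(rng: np.random.Generator) -> PKParameters:
    """Well-separated random micro-constants for oracle comparisons."""
    return PKParameters(
        v1=float(rng.uniform(3, 20)),
        k10=float(rng.uniform(0.02, 0.2)),
        k12=float(rng.uniform(0.1, 0.6)),
        k21=float(rng.uniform(0.05, 0.4)),
        k13=float(rng.uniform(0.05, 0.3)),
        k31=float(rng.uniform(0.005, 0.05)),
        ke0=float(rng.uniform(0.05, 0.5)),
    )


def random_history(rng: np.random.Generator, n_events: int, horizon: float = 600.0) -> DosingHistory:
    times = np.sort(rng.uniform(0, horizon * 0.8, size=n_events - 1))
    events = [DoseEvent(0.0, float(rng.uniform(50, 200)), "initial_bolus")]
    events += [DoseEvent(float(t), float(rng.uniform(10, 40))) for t in times]
    return DosingHistory("r", events, horizon)
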