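import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from spnlab.epoching import (
    average_conditions,
    baseline_correct,
    filter_correct,
    rereference_average,
)
from spnlab.montage import (
    ElectrodeMontage,
    build_neighbor_graph,
    packaged_montage,
)
from spnlab.synthetic_data import (
    EpochSet,
    SimulationConfig,
    simulate_behavior,
    simulate_epochs,
)

POSTERIOR_16 = (
    "O1", "O2", "Oz", "PO3", "PO4", "PO7", "PO8", "POz",
    "P3", "P4", "Pz", "P7", "P8", "Cz", "Fz", "Fp1",
)


@pytest.fixture(scope="session")
def montage64():
    return packaged_montage()


@pytest.fixture(scope="session")
def graph64(montage64):
    return build_neighbor_graph(montage64, 35.0)


@pytest.fixture(scope="session")
def montage16(montage64):
    """16-channel posterior sub-montage for fast simulations."""
    idx = [montage64.index(l) for l in POSTERIOR_16]
    return ElectrodeMontage(labels=POSTERIOR_16, coords=montage64.coords[idx])


@pytest.fixture(scope="session")
def graph16(montage16):
    return build_neighbor_graph(montage16, 35.0)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced cohort for fast unit tests (not the study conditions)."""
    return SimulationConfig(
        n_participants=6,
        n_trials=24,
        epoch_span_ms=(-200.0, 800.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg, montage16):
    behavior = simulate_behavior(small_cfg)
    epochs = simulate_epochs(small_cfg, montage16, behavior)
    return behavior, epochs


@pytest.fixture(scope="session")
def small_erps(small_dataset):
    behavior, epochs = small_dataset
    cleaned = filter_correct(
        rereference_average(baseline_correct(epochs)), behavior
    )
    return average_conditions(cleaned)


def make_epochs(
    data: np.ndarray,
    fs_hz: float = 256.0,
    t0_ms: float = -200.0,
    channels=None,
    conditions=None,
    correct=None,
) -> EpochSet:
    """Hand-built EpochSet for unit tests; data is (P, T, C, S)."""
    P, T, C, S = data.shape
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(C))
    times = t0_ms + np.arange(S) * 1000.0 / fs_hz
    if conditions is None:
        conditions = np.tile(
            np.array(["S", "A"] * (T // 2 + 1))[:T], (P, 1)
        )
    if correct is None:
        correct = np.ones((P, T), dtype=bool)
    return EpochSet(
        data=np.asarray(data, dtype=np.float32),
        times_ms=times,
        fs_hz=fs_hz,
        channels=tuple(channels),
        participants=tuple(range(P)),
        conditions=np.asarray(conditions),
        correct=np.asarray(correct, dtype=bool),
    )
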