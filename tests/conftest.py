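import numpy as np
import pytest

from erpdecode import EpochedDataset, SimConfig, TrialInfo, times_axis


@pytest.fixture
def tiny_config() -> SimConfig:
    """Small but structurally faithful study: 6 participants, 16 channels."""
    return SimConfig(
        n_participants=6,
        group_sizes=(2, 2, 2),
        n_images=30,
        n_channels=16,
        sampling_rate=128.0,
    )


def make_dataset(
    n_trials: int = 12,
    n_channels: int = 4,
    sampling_rate: float = 100.0,
    epoch_span: tuple[float, float] = (-100.0, 400.0),
    voltages: np.ndarray | None = None,
    dimension: str = "appealing",
    responses: list[str] | None = None,
    ratings: list[int] | None = None,
    seed: int = 0,
) -> EpochedDataset:
    times = times_axis(epoch_span, sampling_rate)
    if voltages is None:
        rng = np.random.default_rng(seed)
        voltages = rng.standard_normal((n_trials, n_channels, times.size))
    n_trials = voltages.shape[0]
    if responses is None:
        responses = ["yes" if i % 2 else "no" for i in range(n_trials)]
    if ratings is None:
        ratings = [min(100, 10 * i) for i in range(n_trials)]
    trials = [
        TrialInfo(
            image_id=f"img-{i:03d}",
            dimension=dimension,
            response=responses[i],
            rating=ratings[i],
        )
        for i in range(n_trials)
    ]
    return EpochedDataset(
        participant_id="sub-01",
        voltages=voltages,
        times=times,
        channel_labels=tuple(f"CH{i:02d}" for i in range(voltages.shape[1])),
        sampling_rate=sampling_rate,
        trials=trials,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
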