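import numpy as np
import pytest

from vigilwatch import synthetic as syn


@pytest.fixture(scope="session")
def small_montage():
    return ["Fpz", "Fz", "F3", "F4", "Pz", "P3", "P4", "Oz"]


@pytest.fixture(scope="session")
def quiet_spec(small_montage):
    """Blink-free 2-minute recording spec used by several spectral tests."""
    return syn.SimulationSpec(
        channel_labels=small_montage,
        sampling_rate=250.0,
        duration=120.0,
        iaf=10.0,
        blink_rate=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def quiet_recording(quiet_spec):
    rec, gt = syn.generate_recording(quiet_spec)
    return rec, gt


def make_epochs(data, fs=250.0, epoch_length=2.0, step=2.0):
    """Build an EpochSet directly from an (epoch, channel, sample) array."""
    from vigilwatch.preprocessing import EpochSet

    data = np.asarray(data, dtype=np.float32)
    return EpochSet(
        epochs=data,
        sampling_rate=fs,
        channel_labels=[f"CH{i}" for i in range(data.shape[1])],
        epoch_length=epoch_length,
        step=step,
        start_times=np.arange(data.shape[0]) * step,
    )
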