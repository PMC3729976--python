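import numpy as np
import pytest

from oscmmn.containers import EpochSet
from oscmmn.layout import standard_layout


def make_epochs(data, fs=1000.0, t0=-300.0, condition=None, names=None, positions=None):
    """Wrap a (trials, channels, times) array in an EpochSet with the
    idealized layout's leading channels."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, _ = data.shape
    if names is None or positions is None:
        all_names, all_pos = standard_layout(64)
        names = all_names[:n_ch] if names is None else names
        positions = all_pos[:n_ch] if positions is None else positions
    if condition is None:
        condition = np.array(["standard"] * n_tr, dtype=object)
    return EpochSet(
        data=data,
        sampling_rate_hz=fs,
        t0_offset_ms=t0,
        condition=np.asarray(condition, dtype=object),
        channel_names=list(names),
        channel_positions=np.asarray(positions),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def epochs_maker():
    return make_epochs
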