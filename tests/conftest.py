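import numpy as np
import pytest

from teplab import ERP, ProtocolConfig, SubjectTruth


def make_erp(
    data,
    sampling_rate=1000.0,
    t_start_ms=-200.0,
    channel_names=None,
    condition="single",
    cs_offset_ms=None,
    subject_id="sub",
):
    """Build an ERP on a uniform grid starting at t_start_ms (snapped to it)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n0 = round(t_start_ms * sampling_rate / 1000.0)
    t = (np.arange(data.shape[1]) + n0) * 1000.0 / sampling_rate
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ERP(
        subject_id=subject_id,
        condition=condition,
        channel_names=channel_names,
        sampling_rate=sampling_rate,
        time_axis=t,
        data=data,
        n_trials_averaged=1,
        cs_offset_ms=cs_offset_ms,
    )


@pytest.fixture
def fast_protocol():
    """Reduced-rate protocol for cheap EEG unit tests."""
    return ProtocolConfig(sampling_rate=512.0, epoch_window=(-450.0, 350.0))


@pytest.fixture
def noiseless_truth():
    return SubjectTruth("s0", "NU", lici_true=30.0, noise_sd=0.0)
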