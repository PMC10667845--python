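import numpy as np
import pandas as pd
import pytest

from flexephys.session import ChannelInfo, RecordingSession, SortedUnit, snippet_length
from flexephys.synthetic import biphasic_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_unit(unit_id="u000", n_spikes=50, fs=20_000.0, duration=60.0,
              amplitude=-90.0, noise_sd=2.0, channel=0, seed=0, isolation=None,
              noise_overlap=None):
    """A well-behaved sorted unit with template + noise snippets."""
    r = np.random.default_rng(seed)
    times = np.sort(r.uniform(0.5, duration - 0.5, n_spikes))
    times += np.arange(n_spikes) * 1e-9  # guarantee strict monotonicity
    tmpl = biphasic_template(fs, amplitude_uv=amplitude)
    wf = tmpl[None, :] + r.normal(0, noise_sd, (n_spikes, tmpl.size))
    return SortedUnit(unit_id=unit_id, spike_times=times, primary_channel=channel,
                      waveforms=wf, isolation=isolation, noise_overlap=noise_overlap)


def make_session(n_units=2, fs=20_000.0, duration=60.0, seed=0, with_raw=False):
    units = [make_unit(f"u{i:03d}", channel=i, seed=seed + i, duration=duration, fs=fs)
             for i in range(n_units)]
    channels = [ChannelInfo(i, "A", 100.0 + 30.0 * i, (0.0, 30.0 * i)) for i in range(4)]
    trials = pd.DataFrame({
        "trial_id": [0, 1],
        "onset_s": [1.0, 3.0],
        "offset_s": [2.0, 4.0],
        "orientation_deg": [0.0, 90.0],
    })
    raw = None
    if with_raw:
        raw = np.random.default_rng(seed).normal(0, 5, (2, 4)).astype(np.float32)
    return RecordingSession(
        session_id=f"sess-{seed}", sampling_rate=fs, duration_s=duration,
        channels=channels, raw=raw, trials=trials, units=units, day_post_implant=10,
    )


@pytest.fixture
def session():
    return make_session()


@pytest.fixture
def snip_len():
    return snippet_length(20_000.0)
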