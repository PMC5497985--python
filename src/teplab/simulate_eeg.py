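"""Synthetic TMS-evoked EEG epochs with known ground truth.

The canonical TEP is a causal sum of Gaussian-windowed damped sinusoids at
fixed post-pulse latencies, with a dominant component inside the 15-40 ms
early-TEP window and further components spanning the 50-150 ms LICI window.
Each channel scales the template by a spatial falloff from the coil
centroid. Paired-pulse epochs superpose the conditioning-pulse (CS)
response at the grid-aligned CS offset and a test-pulse (TS) response whose
waveform is multiplied by (1 - lici_true/100). Noise is white Gaussian per
sample by default; optional 1/f ("pink") coloring and an exponential decay
artifact are available for robustness studies.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochSet
from .errors import SpecError, WindowError
from .protocol import ProtocolConfig, channel_gains
from .truth import SubjectTruth

#: Canonical TEP components: (latency_ms, amplitude_uV, freq_hz, sigma_ms).
#: The 25 ms component dominates the early-TEP window; the 60 and 100 ms
#: components give the LICI window (50-150 ms) a measurable response.
TEP_COMPONENTS: tuple[tuple[float, float, float, float], ...] = (
    (25.0, 10.0, 35.0, 7.0),
    (60.0, -8.0, 14.0, 14.0),
    (100.0, 6.0, 9.0, 22.0),
    (185.0, -3.0, 5.0, 40.0),
)


def tep_template(t_ms: np.ndarray) -> np.ndarray:
    """Canonical single-pulse TEP (µV) at times ``t_ms`` after pulse onset.

    Causal: identically zero for t < 0.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    for lat, amp, freq, sigma in TEP_COMPONENTS:
        phase = 2.0 * np.pi * freq * (t - lat) / 1000.0
        out += amp * np.exp(-0.5 * ((t - lat) / sigma) ** 2) * np.cos(phase)
    out[t < 0] = 0.0
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-amplitude noise along the last axis, scaled to the requested sd."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    weights = np.zeros_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    colored = np.fft.irfft(spec * weights, n=shape[-1], axis=-1)
    scale = colored.std()
    if scale > 0:
        colored *= sd / scale
    return colored


def simulate_tep_epochs(
    truth: SubjectTruth,
    protocol: ProtocolConfig | None = None,
    seed: int = 0,
    noise_color: str = "white",
    decay_artifact_uv: float = 0.0,
    decay_tau_ms: float = 30.0,
) -> tuple[EpochSet, EpochSet]:
    """Simulate one subject's single- and paired-pulse epoch sets.

    Returns ``(single, paired)`` with ``protocol.n_single`` and
    ``protocol.n_paired`` trials. With ``noise_sd = 0`` the paired epochs'
    TS-locked component equals exactly ``(1 - lici_true/100)`` times the
    single-pulse template, superposed on the CS response.
    """
    protocol = protocol or ProtocolConfig()
    t = protocol.time_axis()
    cs_ms = protocol.cs_offset_ms  # negative, exactly on the grid
    if t[0] > cs_ms or t[-1] < protocol.lici_window[1]:
        raise WindowError(
            f"epoch window {protocol.epoch_window} too short to contain the CS time "
            f"({cs_ms:.3f} ms) and the LICI window end ({protocol.lici_window[1]} ms)"
        )
    if noise_color not in ("white", "pink"):
        raise SpecError(f"noise_color must be 'white' or 'pink', got {noise_color!r}")

    gains = channel_gains(protocol.channel_names, protocol.coil_channels)
    rng = np.random.default_rng(seed)

    base = truth.tep_amplitude_scale * tep_template(t)
    if decay_artifact_uv:
        base = base + decay_artifact_uv * np.where(
            t >= 0, np.exp(-np.maximum(t, 0.0) / decay_tau_ms), 0.0
        )
    ts_scale = 1.0 - truth.lici_true / 100.0
    cs_response = truth.tep_amplitude_scale * tep_template(t - cs_ms)
    if decay_artifact_uv:
        tc = t - cs_ms
        cs_response = cs_response + decay_artifact_uv * np.where(
            tc >= 0, np.exp(-np.maximum(tc, 0.0) / decay_tau_ms), 0.0
        )

    single_mean = gains[:, None] * base[None, :]
    paired_mean = gains[:, None] * (cs_response + ts_scale * base)[None, :]

    def _noise(n_trials: int) -> np.ndarray:
        shape = (len(gains), n_trials, t.size)
        if truth.noise_sd == 0:
            return np.zeros(shape).transpose(0, 2, 1)
        if noise_color == "pink":
            raw = _pink_noise(rng, shape, truth.noise_sd)
        else:
            raw = rng.normal(0.0, truth.noise_sd, size=shape)
        return raw.transpose(0, 2, 1)  # -> (channels, times, trials)

    single = EpochSet(
        subject_id=truth.subject_id,
        condition="single",
        channel_names=protocol.channel_names,
        sampling_rate=protocol.sampling_rate,
        time_axis=t,
        data=single_mean[:, :, None] + _noise(protocol.n_single),
    )
    paired = EpochSet(
        subject_id=truth.subject_id,
        condition="paired",
        channel_names=protocol.channel_names,
        sampling_rate=protocol.sampling_rate,
        time_axis=t,
        data=paired_mean[:, :, None] + _noise(protocol.n_paired),
        cs_offset_ms=cs_ms,
    )
    return single, paired
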