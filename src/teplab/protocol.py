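"""Stimulation-protocol description and the default recording montage.

The defaults mirror a paired-pulse LICI protocol over the right prefrontal
cortex: 2048 Hz sampling, 50 single + 50 paired pulses, a 100 ms
conditioning-to-test (CS-TS) interval, and the four electrodes under the
coil center (FC4, FC6, F4, F6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError

#: Approximate 2-D scalp positions (right-frontal quadrant of a 10-20 layout,
#: head radius ~ 1). Only relative distances matter: they drive the spatial
#: falloff of the simulated TEP away from the coil.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "FC4": (0.42, 0.28),
    "FC6": (0.62, 0.26),
    "F4": (0.38, 0.55),
    "F6": (0.56, 0.52),
    "F2": (0.19, 0.57),
    "FC2": (0.21, 0.29),
    "C4": (0.45, 0.00),
    "C6": (0.67, 0.00),
    "AF4": (0.28, 0.75),
    "F8": (0.72, 0.48),
}

DEFAULT_COIL_CHANNELS = ("FC4", "FC6", "F4", "F6")
DEFAULT_CHANNELS = tuple(CHANNEL_POSITIONS)


@dataclass(frozen=True)
class ProtocolConfig:
    """TMS-EEG acquisition parameters used by the simulator and pipeline.

    Parameters
    ----------
    sampling_rate : float
        Recording frequency in Hz.
    epoch_window : tuple of float
        (start_ms, end_ms) of the epoch relative to test-pulse onset. Must
        span the CS time (-cs_ts_interval_ms) and the end of the LICI
        analysis window.
    n_single, n_paired : int
        Trials per condition.
    cs_ts_interval_ms : float
        Conditioning-to-test pulse interval.
    channel_names, coil_channels : tuple of str
        Recorded electrodes and the subset under the coil center.
    """

    sampling_rate: float = 2048.0
    epoch_window: tuple[float, float] = (-500.0, 500.0)
    n_single: int = 50
    n_paired: int = 50
    cs_ts_interval_ms: float = 100.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    coil_channels: tuple[str, ...] = DEFAULT_COIL_CHANNELS
    lici_window: tuple[float, float] = (50.0, 150.0)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SpecError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.n_single < 1 or self.n_paired < 1:
            raise SpecError("n_single and n_paired must be >= 1")
        unknown = set(self.coil_channels) - set(self.channel_names)
        if unknown:
            raise SpecError(f"coil_channels not in channel_names: {sorted(unknown)}")
        start, end = self.epoch_window
        if start >= end:
            raise SpecError(f"epoch_window start must precede end, got {self.epoch_window}")
        if start > -self.cs_ts_interval_ms or end < self.lici_window[1]:
            raise SpecError(
                "epoch_window must span the CS time "
                f"(-{self.cs_ts_interval_ms} ms) and the LICI window end "
                f"({self.lici_window[1]} ms); got {self.epoch_window}"
            )

    @property
    def cs_offset_samples(self) -> int:
        """CS-TS interval rounded to whole samples (the realized offset)."""
        return int(round(self.cs_ts_interval_ms * self.sampling_rate / 1000.0))

    @property
    def cs_offset_ms(self) -> float:
        """CS time actually used, in ms (exactly on the sample grid)."""
        return -self.cs_offset_samples * 1000.0 / self.sampling_rate

    def time_axis(self) -> np.ndarray:
        """Uniform time grid (ms) with t = 0 exactly on a sample."""
        fs = self.sampling_rate
        n0 = math.floor(self.epoch_window[0] * fs / 1000.0)
        n1 = math.ceil(self.epoch_window[1] * fs / 1000.0)
        return np.arange(n0, n1 + 1) * (1000.0 / fs)


def channel_gains(
    channel_names: tuple[str, ...],
    coil_channels: tuple[str, ...],
    falloff_scale: float = 0.35,
) -> np.ndarray:
    """Spatial gain per channel: exp(-d / falloff_scale) from the coil centroid.

    Channels without a known position get the weakest listed gain.
    """
    coil_xy = np.array([CHANNEL_POSITIONS[c] for c in coil_channels if c in CHANNEL_POSITIONS])
    center = coil_xy.mean(axis=0)
    known = [CHANNEL_POSITIONS.get(c) for c in channel_names]
    dmax = max(
        (float(np.hypot(*(np.asarray(p) - center))) for p in known if p is not None),
        default=0.0,
    )
    gains = np.empty(len(channel_names))
    for i, pos in enumerate(known):
        d = dmax if pos is None else float(np.hypot(*(np.asarray(pos) - center)))
        gains[i] = np.exp(-d / falloff_scale)
    return gains
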