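"""In-memory containers for epoched TMS-EEG data and trial-averaged ERPs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, SpecError

_GRID_ATOL = 1e-9


def _check_grid(time_axis: np.ndarray, sampling_rate: float) -> None:
    if time_axis.ndim != 1 or time_axis.size < 2:
        raise SpecError("time_axis must be 1-D with at least 2 samples")
    steps = np.diff(time_axis)
    expected = 1000.0 / sampling_rate
    if np.any(steps <= 0) or not np.allclose(steps, expected, atol=1e-6):
        raise SpecError(
            f"time_axis must be strictly increasing with uniform step {expected:.6f} ms"
        )


@dataclass
class EpochSet:
    """Epoched voltage traces time-locked to the test pulse (t = 0).

    ``data`` is (n_channels, n_times, n_trials) in µV. For paired-pulse
    epochs ``cs_offset_ms`` records where the conditioning pulse sits
    (negative, nominally -100 ms, realized on the sample grid).
    """

    subject_id: str
    condition: str  # "single" | "paired"
    channel_names: tuple[str, ...]
    sampling_rate: float
    time_axis: np.ndarray
    data: np.ndarray
    cs_offset_ms: float | None = None

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.condition not in ("single", "paired"):
            raise SpecError(f"condition must be 'single' or 'paired', got {self.condition!r}")
        _check_grid(self.time_axis, self.sampling_rate)
        if self.data.ndim != 3:
            raise SpecError("data must be (channels, times, trials)")
        if self.data.shape[0] != len(self.channel_names):
            raise SpecError("data channel axis does not match channel_names")
        if self.data.shape[1] != self.time_axis.size:
            raise SpecError("data time axis does not match time_axis")
        if self.data.shape[2] < 1:
            raise SpecError("need at least one trial")
        if not np.all(np.isfinite(self.data)):
            raise SpecError("data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


@dataclass
class ERP:
    """Trial-averaged waveform, (n_channels, n_times) in µV.

    ``valid_mask`` (per time sample) marks samples that carry defined
    values; shift-subtraction leaves a tail of undefined samples which are
    carried through unmodified but flagged here. ``None`` means all valid.
    """

    subject_id: str
    condition: str
    channel_names: tuple[str, ...]
    sampling_rate: float
    time_axis: np.ndarray
    data: np.ndarray
    n_trials_averaged: int
    cs_offset_ms: float | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        _check_grid(self.time_axis, self.sampling_rate)
        if self.data.shape != (len(self.channel_names), self.time_axis.size):
            raise SpecError("ERP data must be (channels, times) matching metadata")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.time_axis.shape:
                raise SpecError("valid_mask must match time_axis")

    def valid(self) -> np.ndarray:
        if self.valid_mask is None:
            return np.ones_like(self.time_axis, dtype=bool)
        return self.valid_mask


def check_same_grid(a: ERP, b: ERP) -> None:
    """Raise :class:`GridMismatchError` unless two ERPs share grid + channels."""
    if a.channel_names != b.channel_names:
        raise GridMismatchError("channel sets differ")
    if a.time_axis.shape != b.time_axis.shape or not np.allclose(
        a.time_axis, b.time_axis, atol=_GRID_ATOL
    ):
        raise GridMismatchError("time grids differ")
    if abs(a.sampling_rate - b.sampling_rate) > _GRID_ATOL:
        raise GridMismatchError("sampling rates differ")
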