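"""TMS-evoked potential metrics: early TEP and long-interval cortical inhibition.

Two per-subject measures are computed from epoched single- and paired-pulse
EEG:

* **early TEP** — the rectified average amplitude of the single-pulse ERP
  over 15-40 ms after the pulse, averaged over the electrodes under the
  coil (FC4, FC6, F4, F6); the matching rectified AUC is reported alongside.
* **LICI** — suppression of the test-pulse (TS) response by a conditioning
  pulse (CS) 100 ms earlier. The single-pulse ERP is shifted onto the CS
  time and subtracted from the paired-pulse ERP to remove the lingering CS
  response, then

      LICI = [1 - rectifiedAUC(corrected paired) / rectifiedAUC(single)] * 100

  with both AUCs taken over the same post-TS window (default 50-150 ms) on
  the coil channels. 100 means full suppression, 0 none, negative values
  facilitation.

Conventions: times in ms relative to test-pulse onset; window endpoints are
inclusive; quadrature is the composite trapezoid on the uniform grid;
channel pooling is rectify-per-channel then unweighted channel mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import ERP, EpochSet, check_same_grid
from .errors import DegenerateSignalError, GridMismatchError, WindowError

_EPS = 1e-9

DEFAULT_BASELINE_WINDOW = (-400.0, -110.0)
DEFAULT_EARLY_TEP_WINDOW = (15.0, 40.0)
DEFAULT_LICI_WINDOW = (50.0, 150.0)
#: Samples within (-2, +14) ms of a pulse are treated as artifact and may
#: not enter analysis windows.
PULSE_ARTIFACT_WINDOW = (-2.0, 14.0)


@dataclass
class TEPResult:
    """Per-subject electrophysiological outcome measures."""

    subject_id: str
    early_tep_mean: float  # µV, rectified windowed mean
    early_tep_auc: float  # µV·ms over the same window
    lici_percent: float
    early_tep_window: tuple[float, float] = DEFAULT_EARLY_TEP_WINDOW
    lici_window: tuple[float, float] = DEFAULT_LICI_WINDOW
    channels: tuple[str, ...] = ()


def _window_mask(erp: ERP, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi < lo:
        raise WindowError(f"window start must not exceed end, got {window}")
    mask = (erp.time_axis >= lo - _EPS) & (erp.time_axis <= hi + _EPS)
    mask &= erp.valid()
    if not mask.any():
        raise WindowError(f"no valid samples in window {window}")
    return mask


def _channel_index(erp: ERP, channels) -> np.ndarray:
    channels = tuple(channels)
    missing = [c for c in channels if c not in erp.channel_names]
    if missing:
        raise GridMismatchError(f"channels not present: {missing}")
    return np.array([erp.channel_names.index(c) for c in channels])


def epochs_to_erp(
    epochs: EpochSet, baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
) -> ERP:
    """Average trials and subtract the per-channel baseline mean.

    The baseline window must lie inside the epoch and end before any pulse
    (before the CS for paired epochs), with a 2 ms artifact guard.
    """
    lo, hi = baseline_window
    t = epochs.time_axis
    if lo < t[0] - _EPS or hi > t[-1] + _EPS:
        raise WindowError(f"baseline window {baseline_window} outside epoch")
    first_pulse = epochs.cs_offset_ms if epochs.cs_offset_ms is not None else 0.0
    if hi > first_pulse + PULSE_ARTIFACT_WINDOW[0] + _EPS:
        raise WindowError(
            f"baseline window {baseline_window} overlaps the pulse at {first_pulse:.3f} ms"
        )
    mask = (t >= lo - _EPS) & (t <= hi + _EPS)
    if not mask.any():
        raise WindowError(f"baseline window {baseline_window} contains no samples")
    mean = epochs.data.mean(axis=2)
    baseline = mean[:, mask].mean(axis=1, keepdims=True)
    return ERP(
        subject_id=epochs.subject_id,
        condition=epochs.condition,
        channel_names=epochs.channel_names,
        sampling_rate=epochs.sampling_rate,
        time_axis=t,
        data=mean - baseline,
        n_trials_averaged=epochs.n_trials,
        cs_offset_ms=epochs.cs_offset_ms,
    )


def rectified_window_mean(erp: ERP, window: tuple[float, float], channels) -> float:
    """Mean of |voltage| over the window per channel, then mean over channels."""
    mask = _window_mask(erp, window)
    idx = _channel_index(erp, channels)
    return float(np.abs(erp.data[np.ix_(idx, np.flatnonzero(mask))]).mean(axis=1).mean())


def rectified_auc(erp: ERP, window: tuple[float, float], channels) -> float:
    """Trapezoid integral of |voltage| over the window, channel-averaged (µV·ms)."""
    mask = _window_mask(erp, window)
    cols = np.flatnonzero(mask)
    if cols.size < 2:
        raise WindowError(f"window {window} holds fewer than 2 valid samples")
    idx = _channel_index(erp, channels)
    t = erp.time_axis[cols]
    per_channel = np.trapezoid(np.abs(erp.data[np.ix_(idx, cols)]), x=t, axis=1)
    return float(per_channel.mean())


def shift_subtract(single_erp: ERP, paired_erp: ERP, shift_ms: float = 100.0) -> ERP:
    """Remove the lingering CS response from a paired-pulse ERP.

    The single-pulse ERP is repositioned so its pulse onset coincides with
    the CS time (-shift_ms) and subtracted:
    ``corrected(c, t) = paired(c, t) - single(c, t + shift)``.
    The shift is realized as a whole number of samples (the grid is built so
    the nominal shift rounds to within half a sample). Samples where the
    shifted single ERP is undefined (the trailing ``shift`` samples) are
    carried through unmodified and flagged invalid.
    """
    check_same_grid(single_erp, paired_erp)
    k = int(round(shift_ms * single_erp.sampling_rate / 1000.0))
    if k <= 0:
        raise WindowError(f"shift_ms must be positive, got {shift_ms}")
    n = single_erp.time_axis.size
    if k >= n:
        raise WindowError("shift exceeds epoch length")
    corrected = paired_erp.data.copy()
    corrected[:, : n - k] -= single_erp.data[:, k:]
    valid = np.zeros(n, dtype=bool)
    valid[: n - k] = True
    if single_erp.valid_mask is not None:
        valid[: n - k] &= single_erp.valid_mask[k:]
    valid &= paired_erp.valid()
    return ERP(
        subject_id=paired_erp.subject_id,
        condition="paired_corrected",
        channel_names=paired_erp.channel_names,
        sampling_rate=paired_erp.sampling_rate,
        time_axis=paired_erp.time_axis,
        data=corrected,
        n_trials_averaged=paired_erp.n_trials_averaged,
        cs_offset_ms=paired_erp.cs_offset_ms,
        valid_mask=valid,
    )


def compute_lici(
    single_erp: ERP,
    paired_erp: ERP,
    window: tuple[float, float] = DEFAULT_LICI_WINDOW,
    channels=None,
    shift_ms: float = 100.0,
) -> float:
    """LICI percentage from single- and paired-pulse ERPs (see module docs)."""
    channels = tuple(channels) if channels is not None else single_erp.channel_names
    corrected = shift_subtract(single_erp, paired_erp, shift_ms=shift_ms)
    auc_single = rectified_auc(single_erp, window, channels)
    if auc_single <= 0.0:
        raise DegenerateSignalError(
            "rectified AUC of the single-pulse ERP is zero; LICI undefined"
        )
    auc_paired = rectified_auc(corrected, window, channels)
    return (1.0 - auc_paired / auc_single) * 100.0


@dataclass
class TepConfig:
    """Windows and channels for per-subject TEP metrics."""

    early_tep_window: tuple[float, float] = DEFAULT_EARLY_TEP_WINDOW
    lici_window: tuple[float, float] = DEFAULT_LICI_WINDOW
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
    channels: tuple[str, ...] = ("FC4", "FC6", "F4", "F6")
    shift_ms: float = 100.0


def compute_subject_tep_metrics(
    single: EpochSet, paired: EpochSet, config: TepConfig | None = None
) -> TEPResult:
    """Early TEP (from single-pulse epochs) and LICI for one subject."""
    config = config or TepConfig()
    single_erp = epochs_to_erp(single, config.baseline_window)
    paired_erp = epochs_to_erp(paired, config.baseline_window)
    return TEPResult(
        subject_id=single.subject_id,
        early_tep_mean=rectified_window_mean(
            single_erp, config.early_tep_window, config.channels
        ),
        early_tep_auc=rectified_auc(single_erp, config.early_tep_window, config.channels),
        lici_percent=compute_lici(
            single_erp,
            paired_erp,
            window=config.lici_window,
            channels=config.channels,
            shift_ms=config.shift_ms,
        ),
        early_tep_window=tuple(config.early_tep_window),
        lici_window=tuple(config.lici_window),
        channels=tuple(config.channels),
    )
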