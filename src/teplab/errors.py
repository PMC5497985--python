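"""Exception hierarchy.

All teplab-raised errors derive from :class:`TeplabError` so callers can
catch pipeline problems without masking programming errors.
"""


class TeplabError(Exception):
    """Base class for all teplab errors."""


class WindowError(TeplabError, ValueError):
    """A time window is empty, outside the epoch, or overlaps a pulse."""


class GridMismatchError(TeplabError, ValueError):
    """Two waveforms do not share the same time grid / channel set."""


class DegenerateSignalError(TeplabError, ValueError):
    """A ratio or statistic is undefined (e.g. zero single-pulse AUC)."""


class EstimatorError(TeplabError, ValueError):
    """A behavioral estimator lacks the trials it needs."""


class FormatError(TeplabError, ValueError):
    """An on-disk container is malformed; the message names the field."""


class SpecError(TeplabError, ValueError):
    """A simulation spec violates its invariants (e.g. non-PSD correlations)."""
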