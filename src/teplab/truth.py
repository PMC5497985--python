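"""Ground-truth parameter bundle for one simulated subject."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SpecError


@dataclass
class SubjectTruth:
    """Everything the downstream estimators are asked to recover.

    Units: ``lici_true`` in percent (negative = facilitation), ``noise_sd``
    in µV per sample, RT parameters in ms, ``k_true`` in 1/day,
    ``choice_beta`` in 1/currency (logistic decision-noise slope),
    ``p_arith``/``p_mem`` are single-trial success probabilities.
    """

    subject_id: str
    group: str
    tep_amplitude_scale: float = 1.0
    lici_true: float = 27.0
    noise_sd: float = 3.0
    ssrt_true: float = 240.0
    go_rt_mean: float = 580.0
    go_rt_sd: float = 80.0
    k_true: float = 0.01
    choice_beta: float = 0.5
    p_arith: float = 0.8
    p_mem: float = 0.8
    score_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.go_rt_sd < 0:
            raise SpecError("go_rt_sd must be >= 0")
        if self.k_true < 0:
            raise SpecError("k_true must be >= 0")
        for name in ("p_arith", "p_mem"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {v}")
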