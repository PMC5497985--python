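"""Cohort-level simulation: subjects, EEG epochs, task logs, score tables.

The default cohort emulates a two-group cross-sectional design — 16 heavy
smartphone users (SU) vs 35 nonusers (NU) — with group-level differences on
cortical excitability, discounting, and questionnaire scores in the
directions and approximate magnitudes the estimators are meant to detect.
Questionnaire subscale totals are drawn from a multivariate normal whose
correlation structure is set by explicit (scale_a, scale_b, rho) targets;
a non-positive-semidefinite implied correlation matrix is rejected.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .protocol import ProtocolConfig
from .simulate_behavior import (
    default_choice_set,
    simulate_arithmetic,
    simulate_discounting,
    simulate_memory,
    simulate_stop_signal,
)
from .simulate_eeg import simulate_tep_epochs
from .truth import SubjectTruth

#: SubjectTruth fields drawn per subject. k_true is log-normal (mean taken
#: as the median, sd on the log scale); the rest are normal with clipping
#: to their valid ranges.
_TRUTH_FIELDS = (
    "tep_amplitude_scale",
    "lici_true",
    "noise_sd",
    "ssrt_true",
    "go_rt_mean",
    "go_rt_sd",
    "k_true",
    "choice_beta",
    "p_arith",
    "p_mem",
)

DEFAULT_SCALES = (
    "caars_inattention",
    "caars_hyperactivity",
    "caars_impulsivity",
    "caars_self_concept",
    "caars_adhd_symptoms",
    "caars_adhd_index",
    "cas",
    "bdi",
    "rsms",
    "app_usage",
)


@dataclass
class GroupSpec:
    """Distributional description of one group's subjects."""

    label: str
    n: int
    truth_means: dict[str, float] = field(default_factory=dict)
    truth_sds: dict[str, float] = field(default_factory=dict)
    scale_means: dict[str, float] = field(default_factory=dict)
    scale_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError(f"group {self.label!r}: n must be >= 1")
        for k in list(self.truth_means) + list(self.truth_sds):
            if k not in _TRUTH_FIELDS:
                raise SpecError(f"unknown truth parameter {k!r}")


@dataclass
class CohortSpec:
    """Groups, cross-scale correlation targets, and the master seed."""

    groups: list[GroupSpec]
    correlation_targets: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b, rho in self.correlation_targets:
            if abs(rho) > 1:
                raise SpecError(f"|rho| must be <= 1, got {rho} for ({a}, {b})")

    def scale_names(self) -> list[str]:
        names: list[str] = []
        for g in self.groups:
            for s in g.scale_means:
                if s not in names:
                    names.append(s)
        return names

    def correlation_matrix(self, scale_names: list[str]) -> np.ndarray:
        corr = np.eye(len(scale_names))
        idx = {s: i for i, s in enumerate(scale_names)}
        for a, b, rho in self.correlation_targets:
            if a not in idx or b not in idx:
                raise SpecError(f"correlation target names unknown scale: ({a}, {b})")
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise SpecError(
                f"correlation targets imply a non-positive-semidefinite matrix "
                f"(min eigenvalue {eigmin:.3e})"
            )
        return corr


def _baseline_truth_means() -> dict[str, float]:
    return dict(
        tep_amplitude_scale=1.0,
        lici_true=26.0,
        noise_sd=3.0,
        ssrt_true=240.0,
        go_rt_mean=580.0,
        go_rt_sd=80.0,
        k_true=0.010,  # median (log-normal)
        choice_beta=0.5,
        p_arith=0.80,
        p_mem=0.80,
    )


def _baseline_truth_sds() -> dict[str, float]:
    return dict(
        tep_amplitude_scale=0.15,
        lici_true=6.0,
        noise_sd=0.0,
        ssrt_true=30.0,
        go_rt_mean=50.0,
        go_rt_sd=0.0,
        k_true=0.5,  # sd of ln k
        choice_beta=0.0,
        p_arith=0.12,
        p_mem=0.10,
    )


def _baseline_scale_means() -> dict[str, float]:
    m = {s: 50.0 for s in DEFAULT_SCALES}
    m["bdi"] = 8.0
    m["app_usage"] = 5.0  # weekly launches / 10, arbitrary usage units
    return m


def _baseline_scale_sds() -> dict[str, float]:
    s = {name: 10.0 for name in DEFAULT_SCALES}
    s["bdi"] = 6.0
    s["app_usage"] = 3.0
    return s


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Study-like two-group cohort: SU (n=16) vs NU (n=35) with true effects."""
    nu = GroupSpec(
        label="NU",
        n=35,
        truth_means=_baseline_truth_means(),
        truth_sds=_baseline_truth_sds(),
        scale_means=_baseline_scale_means(),
        scale_sds=_baseline_scale_sds(),
    )
    su_truth = _baseline_truth_means()
    su_truth.update(tep_amplitude_scale=0.91, lici_true=29.0, k_true=0.021, p_arith=0.72)
    su_truth_sds = _baseline_truth_sds()
    su_truth_sds["lici_true"] = 5.0
    su_scales = _baseline_scale_means()
    su_scales.update(
        caars_inattention=54.0,
        caars_hyperactivity=57.0,
        caars_impulsivity=57.5,
        caars_adhd_symptoms=56.0,
        caars_adhd_index=58.0,
        cas=56.0,
        app_usage=40.0,
    )
    su_scale_sds = _baseline_scale_sds()
    su_scale_sds["app_usage"] = 15.0
    su = GroupSpec(
        label="SU",
        n=16,
        truth_means=su_truth,
        truth_sds=su_truth_sds,
        scale_means=su_scales,
        scale_sds=su_scale_sds,
    )
    return CohortSpec(
        groups=[su, nu],
        correlation_targets=[("app_usage", "caars_inattention", 0.5)],
        seed=seed,
    )


def null_cohort_spec(seed: int = 0, n_a: int = 16, n_b: int = 35) -> CohortSpec:
    """Two groups with identical distributions (no true effects)."""
    mk = lambda label, n: GroupSpec(
        label=label,
        n=n,
        truth_means=_baseline_truth_means(),
        truth_sds=_baseline_truth_sds(),
        scale_means=_baseline_scale_means(),
        scale_sds=_baseline_scale_sds(),
    )
    return CohortSpec(groups=[mk("A", n_a), mk("B", n_b)], seed=seed)


@dataclass
class SubjectData:
    truth: SubjectTruth
    epochs_single: object | None = None  # EpochSet
    epochs_paired: object | None = None
    stop_log: pd.DataFrame | None = None
    choice_log: pd.DataFrame | None = None
    arithmetic_log: pd.DataFrame | None = None
    memory_log: pd.DataFrame | None = None


@dataclass
class CohortDataset:
    spec: CohortSpec
    protocol: ProtocolConfig
    subjects: list[SubjectData]
    scores: pd.DataFrame  # one row per subject: subject_id, group, <scales>


def _draw_truth(
    group: GroupSpec, subject_id: str, rng: np.random.Generator, scores: dict[str, float]
) -> SubjectTruth:
    vals: dict[str, float] = {}
    for name in _TRUTH_FIELDS:
        mean = group.truth_means.get(name, _baseline_truth_means()[name])
        sd = group.truth_sds.get(name, 0.0)
        if name == "k_true":
            v = mean * float(np.exp(rng.normal(0.0, sd))) if sd > 0 else mean
        else:
            v = float(rng.normal(mean, sd)) if sd > 0 else mean
        if name in ("p_arith", "p_mem"):
            v = float(np.clip(v, 0.0, 1.0))
        if name in ("noise_sd", "go_rt_sd", "k_true", "choice_beta"):
            v = max(0.0, v)
        if name == "tep_amplitude_scale":
            v = max(0.05, v)
        vals[name] = v
    return SubjectTruth(subject_id=subject_id, group=group.label, score_means=scores, **vals)


def simulate_cohort(
    spec: CohortSpec,
    protocol: ProtocolConfig | None = None,
    include_eeg: bool = True,
    include_behavior: bool = True,
    stop_kwargs: dict | None = None,
    choice_repeats: int = 1,
) -> CohortDataset:
    """Generate a full cohort: deterministic given ``spec.seed``.

    ``include_eeg=False`` / ``include_behavior=False`` skip the expensive
    stages (used for large replicate studies of the score/statistics layer).
    """
    protocol = protocol or ProtocolConfig()
    rng = np.random.default_rng(spec.seed)
    scale_names = spec.scale_names()
    corr = spec.correlation_matrix(scale_names) if scale_names else np.eye(0)
    stop_kwargs = stop_kwargs or {}

    subjects: list[SubjectData] = []
    score_rows: list[dict] = []
    for group in spec.groups:
        means = np.array(
            [group.scale_means.get(s, _baseline_scale_means().get(s, 0.0)) for s in scale_names]
        )
        sds = np.array(
            [group.scale_sds.get(s, _baseline_scale_sds().get(s, 1.0)) for s in scale_names]
        )
        cov = corr * np.outer(sds, sds)
        if scale_names:
            draws = rng.multivariate_normal(means, cov, size=group.n, method="eigh")
        else:
            draws = np.zeros((group.n, 0))
        for j in range(group.n):
            sid = f"{group.label}{j + 1:03d}"
            scores = {s: float(draws[j, i]) for i, s in enumerate(scale_names)}
            truth = _draw_truth(group, sid, rng, scores)
            sub = SubjectData(truth=truth)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if include_eeg:
                sub.epochs_single, sub.epochs_paired = simulate_tep_epochs(
                    truth, protocol, seed=sub_seed
                )
            if include_behavior:
                sub.stop_log = simulate_stop_signal(truth, seed=sub_seed + 1, **stop_kwargs)
                sub.choice_log = simulate_discounting(
                    truth, default_choice_set(choice_repeats), seed=sub_seed + 2
                )
                sub.arithmetic_log = simulate_arithmetic(truth, seed=sub_seed + 3)
                sub.memory_log = simulate_memory(truth, seed=sub_seed + 4)
            subjects.append(sub)
            score_rows.append(dict(subject_id=sid, group=group.label, **scores))
    return CohortDataset(
        spec=copy.deepcopy(spec),
        protocol=protocol,
        subjects=subjects,
        scores=pd.DataFrame(score_rows),
    )
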