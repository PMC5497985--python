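"""Per-subject metric tables: the glue between datasets and group statistics."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .behavior import (
    estimate_ssrt,
    fit_hyperbolic_k,
    score_arithmetic,
    score_memory,
)
from .cohort import CohortDataset, SubjectData
from .io import read_cohort, read_epochs
from .tep import TepConfig, compute_subject_tep_metrics


def tep_metrics_table(dataset: CohortDataset, config: TepConfig | None = None) -> pd.DataFrame:
    """Early TEP and LICI per subject (subjects without EEG are skipped)."""
    rows = []
    for sub in dataset.subjects:
        if sub.epochs_single is None:
            continue
        res = compute_subject_tep_metrics(sub.epochs_single, sub.epochs_paired, config)
        rows.append(
            dict(
                subject_id=sub.truth.subject_id,
                group=sub.truth.group,
                early_tep_mean=res.early_tep_mean,
                early_tep_auc=res.early_tep_auc,
                lici_percent=res.lici_percent,
            )
        )
    return pd.DataFrame(rows)


def tep_metrics_from_dir(cohort_dir: str | Path, config: TepConfig | None = None) -> pd.DataFrame:
    """Streaming variant: loads one subject's epochs at a time."""
    cohort_dir = Path(cohort_dir)
    dataset = read_cohort(cohort_dir, load_eeg=False)
    rows = []
    for sub in dataset.subjects:
        sdir = cohort_dir / "subjects" / sub.truth.subject_id
        if not (sdir / "single.h5").exists():
            continue
        single = read_epochs(sdir / "single.h5")
        paired = read_epochs(sdir / "paired.h5")
        res = compute_subject_tep_metrics(single, paired, config)
        rows.append(
            dict(
                subject_id=sub.truth.subject_id,
                group=sub.truth.group,
                early_tep_mean=res.early_tep_mean,
                early_tep_auc=res.early_tep_auc,
                lici_percent=res.lici_percent,
            )
        )
    return pd.DataFrame(rows)


def _subject_behavior_row(sub: SubjectData, deadline_ms: float = 2000.0,
                          min_valid: int = 3) -> dict:
    row: dict = dict(subject_id=sub.truth.subject_id, group=sub.truth.group)
    if sub.stop_log is not None:
        sst = estimate_ssrt(sub.stop_log)
        row.update(
            ssrt=sst.ssrt,
            mean_go_rt=sst.mean_go_rt,
            mean_ssd=sst.mean_ssd,
            go_error_rate=sst.go_error_rate,
            stop_success_rate=sst.stop_success_rate,
        )
    if sub.choice_log is not None:
        fit = fit_hyperbolic_k(sub.choice_log)
        row.update(k=fit.k, choice_beta=fit.beta, k_converged=fit.converged)
    if sub.arithmetic_log is not None:
        ar = score_arithmetic(sub.arithmetic_log, deadline_ms=deadline_ms, min_valid=min_valid)
        row.update(
            arith_accuracy=ar.accuracy,
            arith_mean_rt=ar.mean_rt,
            arith_discarded=ar.discarded,
        )
    if sub.memory_log is not None:
        mem = score_memory(sub.memory_log)
        row.update(memory_accuracy=mem.accuracy, memory_mean_rt=mem.mean_rt)
    return row


def behavior_metrics_table(dataset: CohortDataset, deadline_ms: float = 2000.0,
                           min_valid: int = 3) -> pd.DataFrame:
    """SSRT, discounting k, arithmetic and memory scores per subject."""
    rows = [
        _subject_behavior_row(sub, deadline_ms, min_valid)
        for sub in dataset.subjects
        if sub.stop_log is not None
        or sub.choice_log is not None
        or sub.arithmetic_log is not None
        or sub.memory_log is not None
    ]
    return pd.DataFrame(rows)
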