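"""On-disk formats.

Epoch container (HDF5): one file per subject/condition with datasets
``data`` (float64, channels x times x trials, µV) and ``time_axis``
(float64, ms), and root attributes ``subject_id``, ``condition``,
``sampling_rate``, ``channel_names`` (UTF-8 string array) and, for paired
epochs, ``cs_offset_ms``. Files are written with HDF5 object timestamps
disabled so identical data produce identical bytes.

Plain-text fallback: a directory with ``meta.json`` (same metadata plus the
time axis) and one ``trial_NNN.csv`` per trial (columns = channels, rows =
samples).

Cohort dataset: a directory with ``manifest.json`` (spec, seed, protocol,
per-subject ground truth), ``scores.csv``, and one subdirectory per subject
holding the epoch containers and the per-task trial logs as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import CohortDataset, CohortSpec, GroupSpec, SubjectData
from .containers import EpochSet
from .errors import FormatError
from .protocol import ProtocolConfig
from .truth import SubjectTruth

_EPOCH_ATTRS = ("subject_id", "condition", "sampling_rate", "channel_names")

TASK_FILES = {
    "stop_log": "stop.csv",
    "choice_log": "discounting.csv",
    "arithmetic_log": "arithmetic.csv",
    "memory_log": "memory.csv",
}


# ---------------------------------------------------------------------------
# Epoch containers


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write the HDF5 epoch container (bit-stable for identical data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("time_axis", data=epochs.time_axis, track_times=False)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["condition"] = epochs.condition
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        if epochs.cs_offset_ms is not None:
            f.attrs["cs_offset_ms"] = float(epochs.cs_offset_ms)


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"epoch container not found: {path}")
    with h5py.File(path, "r") as f:
        for name in _EPOCH_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"epoch container {path} missing attribute {name!r}")
        for ds in ("data", "time_axis"):
            if ds not in f:
                raise FormatError(f"epoch container {path} missing dataset {ds!r}")
        channel_names = tuple(
            c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channel_names"]
        )
        cs = f.attrs.get("cs_offset_ms")
        return EpochSet(
            subject_id=str(f.attrs["subject_id"]),
            condition=str(f.attrs["condition"]),
            channel_names=channel_names,
            sampling_rate=float(f.attrs["sampling_rate"]),
            time_axis=f["time_axis"][()],
            data=f["data"][()],
            cs_offset_ms=float(cs) if cs is not None else None,
        )


def write_epochs_csv(epochs: EpochSet, directory: str | Path) -> None:
    """Plain-text fallback: meta.json + one CSV per trial."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dict(
        subject_id=epochs.subject_id,
        condition=epochs.condition,
        sampling_rate=epochs.sampling_rate,
        channel_names=list(epochs.channel_names),
        cs_offset_ms=epochs.cs_offset_ms,
        n_trials=epochs.n_trials,
        time_axis=epochs.time_axis.tolist(),
    )
    (directory / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=2))
    for k in range(epochs.n_trials):
        pd.DataFrame(
            epochs.data[:, :, k].T, columns=list(epochs.channel_names)
        ).to_csv(directory / f"trial_{k:03d}.csv", index=False)


def read_epochs_csv(directory: str | Path) -> EpochSet:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json in {directory}")
    meta = json.loads(meta_path.read_text())
    for name in ("subject_id", "condition", "sampling_rate", "channel_names", "time_axis"):
        if name not in meta:
            raise FormatError(f"{meta_path} missing field {name!r}")
    trials = []
    for k in range(int(meta["n_trials"])):
        df = pd.read_csv(directory / f"trial_{k:03d}.csv")
        missing = [c for c in meta["channel_names"] if c not in df.columns]
        if missing:
            raise FormatError(f"trial_{k:03d}.csv missing channels {missing}")
        trials.append(df[meta["channel_names"]].to_numpy(float).T)
    return EpochSet(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        channel_names=tuple(meta["channel_names"]),
        sampling_rate=float(meta["sampling_rate"]),
        time_axis=np.asarray(meta["time_axis"], dtype=float),
        data=np.stack(trials, axis=2),
        cs_offset_ms=meta.get("cs_offset_ms"),
    )


# ---------------------------------------------------------------------------
# Cohort dataset directory


def _spec_to_dict(spec: CohortSpec) -> dict:
    return dict(
        seed=spec.seed,
        correlation_targets=[list(t) for t in spec.correlation_targets],
        groups=[dataclasses.asdict(g) for g in spec.groups],
    )


def _spec_from_dict(d: dict) -> CohortSpec:
    return CohortSpec(
        groups=[GroupSpec(**g) for g in d["groups"]],
        correlation_targets=[tuple(t) for t in d.get("correlation_targets", [])],
        seed=int(d.get("seed", 0)),
    )


def write_cohort(dataset: CohortDataset, path: str | Path) -> None:
    path = Path(path)
    (path / "subjects").mkdir(parents=True, exist_ok=True)
    manifest = dict(
        seed=dataset.spec.seed,
        spec=_spec_to_dict(dataset.spec),
        protocol=dataclasses.asdict(dataset.protocol),
        subjects=[
            dict(
                subject_id=s.truth.subject_id,
                group=s.truth.group,
                truth=dataclasses.asdict(s.truth),
                has_eeg=s.epochs_single is not None,
                has_behavior=s.stop_log is not None,
            )
            for s in dataset.subjects
        ],
    )
    (path / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    dataset.scores.to_csv(path / "scores.csv", index=False)
    for s in dataset.subjects:
        sdir = path / "subjects" / s.truth.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        if s.epochs_single is not None:
            write_epochs(s.epochs_single, sdir / "single.h5")
            write_epochs(s.epochs_paired, sdir / "paired.h5")
        for attr, fname in TASK_FILES.items():
            log = getattr(s, attr)
            if log is not None:
                log.to_csv(sdir / fname, index=False)


def read_cohort(path: str | Path, load_eeg: bool = True) -> CohortDataset:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    for name in ("seed", "spec", "protocol", "subjects"):
        if name not in manifest:
            raise FormatError(f"manifest.json missing field {name!r}")
    proto_dict = dict(manifest["protocol"])
    for key in ("epoch_window", "channel_names", "coil_channels", "lici_window"):
        if key in proto_dict:
            proto_dict[key] = tuple(proto_dict[key])
    protocol = ProtocolConfig(**proto_dict)
    subjects = []
    for entry in manifest["subjects"]:
        truth = SubjectTruth(**entry["truth"])
        sdir = path / "subjects" / entry["subject_id"]
        sub = SubjectData(truth=truth)
        if entry.get("has_eeg") and load_eeg:
            sub.epochs_single = read_epochs(sdir / "single.h5")
            sub.epochs_paired = read_epochs(sdir / "paired.h5")
        if entry.get("has_behavior"):
            for attr, fname in TASK_FILES.items():
                setattr(sub, attr, pd.read_csv(sdir / fname))
        subjects.append(sub)
    return CohortDataset(
        spec=_spec_from_dict(manifest["spec"]),
        protocol=protocol,
        subjects=subjects,
        scores=pd.read_csv(path / "scores.csv"),
    )
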