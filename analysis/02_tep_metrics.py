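#!/usr/bin/env python
"""Compute early TEP and LICI for every subject of the simulated cohort.

Reads the cohort written by 01_simulate_cohort.py (streaming one subject's
epochs at a time), applies the full electrophysiological pipeline
(trial averaging, baseline correction, shift-subtract CS removal,
rectified window statistics), and writes results/tep_metrics.csv. Prints
per-group means and the recovery error against the generator's truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from teplab.pipeline import tep_metrics_from_dir

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "tep_metrics.csv")
    args = parser.parse_args()

    table = tep_metrics_from_dir(args.cohort)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    manifest = json.loads((args.cohort / "manifest.json").read_text())
    truth = pd.DataFrame(
        [dict(subject_id=s["subject_id"], lici_true=s["truth"]["lici_true"])
         for s in manifest["subjects"]]
    )
    merged = table.merge(truth, on="subject_id")
    print(f"wrote {len(table)} rows to {args.out}")
    print(merged.groupby("group")[["early_tep_mean", "lici_percent", "lici_true"]]
          .mean().round(2))
    err = (merged["lici_percent"] - merged["lici_true"]).describe()[["mean", "std"]]
    print(f"LICI recovery error: mean {err['mean']:+.2f} pts, sd {err['std']:.2f} "
          "(small negative bias expected: rectified-AUC noise bias)")


if __name__ == "__main__":
    main()
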