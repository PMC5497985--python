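#!/usr/bin/env python
"""Simulate the study-like cohort and write it to disk.

Generates the default two-group cohort — 16 heavy smartphone users (SU) vs
35 nonusers (NU) — with TMS-EEG epochs (50 single + 50 paired pulses at
2048 Hz), stop-signal, discounting, arithmetic and memory logs, and
questionnaire score tables. The epoch containers are large, so the dataset
goes under scratch/; downstream scripts read from there and write their
tables under results/.

Run:  python analysis/01_simulate_cohort.py [--seed 0]
"""

import argparse
import time
from pathlib import Path

import teplab as T

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = parser.parse_args()

    spec = T.default_cohort_spec(seed=args.seed)
    t0 = time.time()
    dataset = T.simulate_cohort(spec)
    T.write_cohort(dataset, args.out)
    n = len(dataset.subjects)
    by_group = dataset.scores["group"].value_counts().to_dict()
    print(f"simulated {n} subjects {by_group} in {time.time() - t0:.1f} s")
    print(f"cohort written to {args.out}")
    print("ground-truth group means (generator):")
    for g in spec.groups:
        print(f"  {g.label}: lici_true={g.truth_means['lici_true']}, "
              f"tep_scale={g.truth_means['tep_amplitude_scale']}, "
              f"k_median={g.truth_means['k_true']}, p_arith={g.truth_means['p_arith']}")


if __name__ == "__main__":
    main()
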