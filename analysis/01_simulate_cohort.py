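#!/usr/bin/env python
"""Simulate the default synthetic cohort and write it to disk.

Generates 110 participants with window-view scenes, sky masks,
subjective ratings, demographics, STADI item responses and
delay-discounting choice logs, with one diverse-sex participant and
2 / 1 missing outcomes injected for the exclusion bookkeeping.

Images and masks go to scratch/cohort (they are bulky and reproducible);
tabular ground truth stays with them.
"""

import argparse
from pathlib import Path

from viewfeat.pipeline import stage_seed
from viewfeat.synthetic import CohortSpec, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    spec = CohortSpec(seed=stage_seed(args.seed, "simulate"))
    cohort = simulate_cohort(spec)
    write_cohort(cohort, args.out)

    n_images = sum(len(p.images) for p in cohort.participants)
    sexes = [p.demographics["sex"] for p in cohort.participants]
    print(f"wrote cohort to {args.out}")
    print(f"participants: {len(cohort.participants)}  images: {n_images} "
          f"(mean {n_images / len(cohort.participants):.2f} per participant)")
    print(f"diverse-sex participants injected: {sexes.count('diverse')}")
    print(f"missing negative-affect outcomes: "
          f"{sum(p.stadi_items is None for p in cohort.participants)}")
    print(f"missing delay-discounting logs: "
          f"{sum(p.choices is None for p in cohort.participants)}")


if __name__ == "__main__":
    main()
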