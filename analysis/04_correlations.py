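#!/usr/bin/env python
"""Assemble the analysis table and compute the Spearman correlation matrix.

Merges features, ratings, demographics and outcomes into one row per
participant, applies the diverse-sex exclusion, and computes the
tie-corrected Spearman matrix over subjective ratings and the 12 usable
low-level features (objective brightness excluded as unreliable).
Prints the subjective-vs-objective agreement checks.
"""

import argparse
from pathlib import Path

import pandas as pd

from viewfeat import stats as S
from viewfeat.pipeline import build_analysis_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    features = pd.read_csv(args.out / "features_per_participant.csv", index_col=0)
    outcomes = pd.read_csv(args.out / "outcomes.csv")
    ratings = pd.read_csv(args.dataset / "ratings.csv")
    demographics = pd.read_csv(args.dataset / "demographics.csv")

    table = build_analysis_table(features, ratings, demographics, outcomes)
    table.to_csv(args.out / "analysis_table.csv", index=False)

    after = S.exclude_participants(table)
    corr_vars = list(S.RATING_VARS) + ["pct_sky"] + list(S.LLVF_USABLE)
    m = S.spearman_matrix(after, corr_vars)
    m.rho.to_csv(args.out / "correlations_rho.csv")
    m.p.to_csv(args.out / "correlations_p.csv")

    print(f"analysis table: {len(table)} rows, "
          f"{len(after)} after diverse-sex exclusion (n = {m.n} complete)")
    for a, b in [
        ("green_ratio", "pct_nature"),
        ("green_ratio", "pct_manmade"),
        ("green_ratio", "green_visibility"),
        ("sky_ratio", "pct_sky"),
        ("quality", "pct_nature"),
    ]:
        print(f"  rho({a}, {b}) = {m.rho.loc[a, b]:+.2f}  (p = {m.p.loc[a, b]:.2g})")


if __name__ == "__main__":
    main()
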