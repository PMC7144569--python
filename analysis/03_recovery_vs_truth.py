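#!/usr/bin/env python
"""Compare fitted group-mean compositions against the generator truth.

Reads the fitted contributions (02_fit_cohorts.py) and the ground-truth
tables (01_simulate_cohorts.py) and tabulates, per excitation × group ×
component, the fitted minus true group-mean percent contribution.  This
quantifies which components the unmixing identifies reliably and which
are limited by band overlap (the arachidonic/oleic pair at 366 nm and
the linoleic/arachidonic/proteins trio at 310 nm are the known
near-degenerate directions).
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scratch", default="scratch")
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    rows = []
    for excitation in (310, 366):
        truth = pd.read_csv(Path(args.scratch) / "cohorts" / f"{excitation}nm"
                            / "truth.csv")
        fitted = pd.read_csv(Path(args.scratch) / f"run_{excitation}nm"
                             / "contributions.tsv", sep="\t")
        tmeans = truth.groupby("group").mean(numeric_only=True)
        fmeans = fitted.groupby("group").mean(numeric_only=True)
        for group in tmeans.index:
            for col in tmeans.columns:
                value = tmeans.loc[group, col]
                if (not col.startswith("percent_") or pd.isna(value)
                        or value < 0):
                    continue
                if col not in fmeans.columns or pd.isna(fmeans.loc[group, col]):
                    continue
                rows.append({
                    "excitation_nm": excitation,
                    "group": group,
                    "component": col[len("percent_"):],
                    "true_mean": tmeans.loc[group, col],
                    "fitted_mean": fmeans.loc[group, col],
                    "error": fmeans.loc[group, col] - tmeans.loc[group, col],
                })
    df = pd.DataFrame(rows)
    path = Path(args.results) / "recovery_vs_truth.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    worst = df.loc[df["error"].abs().idxmax()]
    print(f"\nLargest group-mean error: {worst['component']} at "
          f"{worst['excitation_nm']:.0f} nm / {worst['group']} "
          f"({worst['error']:+.2f} points)")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
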