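#!/usr/bin/env python
"""Derive the twelve climatic-resilience indicators per sow from the Tv
records written by 01_simulate_cohort.py.

Writes results/cr_indicators.tsv and prints the population summary.
"""

import argparse

from crgwas import io
from crgwas.phenotypes import INDICATOR_COLUMNS, HSConfig, derive_all_indicators


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/cr_indicators.tsv")
    args = ap.parse_args()

    tv = io.read_tv_tsv(f"{args.cohort}/tv_series.tsv", f"{args.cohort}/covariates.tsv")
    table = derive_all_indicators(tv, HSConfig())
    io.write_table(table, args.out, index=True)

    print(f"indicators for {len(table)} sows -> {args.out}")
    summary = table[INDICATOR_COLUMNS].describe().loc[["mean", "std", "min", "max"]].T
    print(summary.round(3).to_string())
    n_missing = int(table[INDICATOR_COLUMNS].isna().sum().sum())
    print(f"missing indicator values: {n_missing}")


if __name__ == "__main__":
    main()
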