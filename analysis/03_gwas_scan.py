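#!/usr/bin/env python
"""Mixed-linear-model LOCO association scan for every CR indicator.

LD-prunes the panel, builds the three significance-threshold schemes
(genome-wide Bonferroni 0.05/N, suggestive 1/N, chromosome-wise 0.05/Me),
scans the 12 indicators, and reports genomic inflation and the significant
SNPs.  Writes per-indicator association/Q-Q tables plus thresholds.tsv and
lambda.tsv under results/gwas/.
"""

import argparse

import pandas as pd

from crgwas import io
from crgwas.gwas import qq_table
from crgwas.pipeline import NA_ALL, GwasConfig, run_gwas_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--phenotypes", default="results/cr_indicators.tsv")
    ap.add_argument("--out", default="results/gwas")
    args = ap.parse_args()

    genotypes = io.read_plink_text(
        f"{args.cohort}/genotypes.map", f"{args.cohort}/genotypes.ped"
    )
    pheno = io.read_phenotype_tsv(args.phenotypes)
    scans, thresholds, inflation = run_gwas_stage(pheno, genotypes, GwasConfig())

    for ind, assoc in scans.items():
        io.write_table(assoc, f"{args.out}/assoc_{ind}.tsv")
        io.write_table(qq_table(assoc["p"].dropna().to_numpy()), f"{args.out}/qq_{ind}.tsv")
    rows = [
        dict(level="bonferroni", chromosome=NA_ALL, threshold=thresholds.bonferroni),
        dict(level="suggestive", chromosome=NA_ALL, threshold=thresholds.suggestive),
    ] + [
        dict(level="chromosome_wise", chromosome=c, threshold=t)
        for c, t in thresholds.chromosome_wise.items()
    ]
    io.write_table(pd.DataFrame(rows), f"{args.out}/thresholds.tsv")
    lam = pd.DataFrame(
        [dict(indicator=i, **{"lambda": r.lam}, ci_low=r.ci95[0], ci_high=r.ci95[1])
         for i, r in inflation.items()]
    )
    io.write_table(lam, f"{args.out}/lambda.tsv")

    print(f"N after LD pruning: {thresholds.n_independent_snps}")
    print(f"genome-wide threshold 0.05/N = {thresholds.bonferroni:.3e}; "
          f"suggestive 1/N = {thresholds.suggestive:.3e}")
    print("lambda per indicator:")
    print(lam.round(3).to_string(index=False))
    sig = pd.concat(
        [a.loc[a["sig_suggestive"]].assign(indicator=i) for i, a in scans.items()],
        ignore_index=True,
    )
    print(f"{len(sig)} suggestive associations "
          f"({int(sig['sig_bonferroni'].sum())} genome-wide, "
          f"{int(sig['sig_chromosome_wise'].sum())} chromosome-wise)")
    if len(sig):
        cols = ["indicator", "snp", "chrom", "bp", "freq", "p"]
        print(sig[cols].sort_values("p").head(10).to_string(index=False))
        io.write_table(sig, f"{args.out}/significant_snps.tsv")


if __name__ == "__main__":
    main()
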