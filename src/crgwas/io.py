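"""Text-format readers and writers: PLINK MAP/PED, tidy TSV tables.

All tables are written with headers and ``NA`` for missing values.  The
PLINK writer codes the counted (minor) allele as the SNP map's ``a1``
letter, so write -> read round-trips the dosage matrix exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotypes import TvSeries
from .simulate import EnvironmentSeries, GenotypeMatrix, TruthRecord

log = logging.getLogger(__name__)

NA = "NA"


def write_plink_text(genotypes: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write PLINK text MAP/PED files.

    MAP columns: chromosome, snp id, cM (bp/1e6), bp.  PED rows: family id,
    individual id, zeroed parents/sex/phenotype, then one allele pair per
    SNP (counted allele ``a1``; missing dosage -> ``0 0``).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    sm = genotypes.snp_map
    with open(map_path, "w") as fh:
        for row in sm.itertuples():
            fh.write(f"{row.chrom}\t{row.snp}\t{row.bp / 1e6:.6f}\t{row.bp}\n")
    a1 = sm["a1"].to_numpy()
    a2 = sm["a2"].to_numpy()
    pair = {
        0.0: [a2, a2],
        1.0: [a1, a2],
        2.0: [a1, a1],
    }
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(genotypes.animal_ids):
            fields = [aid, aid, "0", "0", "0", "-9"]
            dos = genotypes.dosage[i]
            for j in range(len(sm)):
                if np.isnan(dos[j]):
                    fields += ["0", "0"]
                else:
                    x, y = pair[dos[j]]
                    fields += [x[j], y[j]]
            fh.write(" ".join(fields) + "\n")
    return map_path, ped_path


def read_plink_text(map_path, ped_path) -> GenotypeMatrix:
    """Read whitespace-delimited PLINK text MAP/PED into a dosage matrix.

    Allele pairs become the dosage of the minor allele (sample frequency;
    ties broken by alphabetical order); ``0 0`` becomes a missing marker
    (NaN).  Mean imputation is left to the association layer.
    """
    snp_map = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp"],
    ).drop(columns="cm")
    m = len(snp_map)
    animal_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            n_alleles = len(parts) - 6
            if n_alleles % 2:
                raise ValueError(f"{ped_path}: line {lineno}: odd allele count ({n_alleles})")
            if n_alleles != 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno}: {n_alleles // 2} genotypes but MAP has {m} SNPs"
                )
            animal_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype="U8"))
    alleles = np.stack(allele_rows) if allele_rows else np.empty((0, 2 * m), dtype="U8")
    first = alleles[:, 0::2]
    second = alleles[:, 1::2]
    n = len(animal_ids)

    dosage = np.full((n, m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        col = np.concatenate([first[:, j], second[:, j]])
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) == 0:
            a1, a2 = "A", "B"
        elif len(uniq) == 1:
            a1, a2 = str(uniq[0]), "0"
        elif len(uniq) == 2:
            # minor allele = lower count; ties -> alphabetical
            order = np.lexsort((uniq, counts))
            a1, a2 = str(uniq[order[0]]), str(uniq[order[1]])
        else:
            raise ValueError(f"SNP {snp_map['snp'].iloc[j]}: more than two alleles")
        a1_list.append(a1)
        a2_list.append(a2)
        miss = (first[:, j] == "0") | (second[:, j] == "0")
        dosage[:, j] = (first[:, j] == a1).astype(float) + (second[:, j] == a1)
        dosage[miss, j] = np.nan
    snp_map["a1"] = a1_list
    snp_map["a2"] = a2_list
    return GenotypeMatrix(dosage=dosage, snp_map=snp_map, animal_ids=animal_ids)


# ---------------------------------------------------------------------------
# tidy TSV


def write_tv_tsv(series: list[TvSeries], path) -> Path:
    """Tidy Tv table: animal_id, timestamp (ISO-8601), tv_celsius."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {"animal_id": s.animal_id, "timestamp": s.timestamps.astype(str), "tv_celsius": s.tv}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, na_rep=NA)
    return path


def write_covariates_tsv(series: list[TvSeries], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in series],
            "ventilation": [s.ventilation for s in series],
            "parity": [s.parity for s in series],
            "barn": [s.barn_id for s in series],
        }
    ).to_csv(path, sep="\t", index=False, na_rep=NA)
    return path


def read_tv_tsv(tv_path, covariates_path) -> list[TvSeries]:
    """Rebuild per-animal TvSeries from the tidy Tv + covariate tables."""
    tv = pd.read_csv(tv_path, sep="\t", parse_dates=["timestamp"])
    cov = pd.read_csv(covariates_path, sep="\t").set_index("animal_id")
    out = []
    for aid, grp in tv.groupby("animal_id", sort=False):
        if aid not in cov.index:
            raise ValueError(f"animal {aid!r} missing from covariate table")
        c = cov.loc[aid]
        grp = grp.sort_values("timestamp")
        out.append(
            TvSeries(
                animal_id=str(aid),
                timestamps=grp["timestamp"].to_numpy().astype("datetime64[m]"),
                tv=grp["tv_celsius"].to_numpy(dtype=float),
                ventilation=str(c["ventilation"]),
                parity=int(c["parity"]),
                barn_id=str(c.get("barn", "")),
            )
        )
    return out


def write_environment_tsv(env: EnvironmentSeries, path) -> Path:
    path = Path(path)
    env.to_frame().to_csv(path, sep="\t", index=False, na_rep=NA)
    return path


def write_truth_tsv(truth: TruthRecord, animal_ids: list[str], path) -> Path:
    path = Path(path)
    truth.to_frame(animal_ids).to_csv(path, sep="\t", index=False, na_rep=NA)
    return path


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep=NA)
    return path


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA]).set_index("animal_id")
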