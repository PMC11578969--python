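"""Positional candidate-gene and QTL-interval lookup around significant SNPs.

A feature (gene or QTL interval) is a hit for a SNP when its interval
intersects the window [snp - flank, snp + flank] on the same chromosome,
inclusive at exactly the flank distance (default 500 kb each side).  QTL
hits are tallied by type (distinct intervals only) and can be tested for
enrichment against a background QTL table with an upper-tail hypergeometric
test.

Coordinates are 1-based inclusive throughout (PLINK/GFF convention).
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "gene_name", "chromosome", "start", "end", "biotype"]
QTL_COLUMNS = ["chromosome", "start", "end", "qtl_type", "trait_name"]
#: distinctness key for QTL intervals
QTL_KEY = ["chromosome", "start", "end", "qtl_type", "trait_name"]

_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "ncrna": "ncRNA",
    "lncrna": "ncRNA",
    "mirna": "ncRNA",
    "snorna": "ncRNA",
    "snrna": "ncRNA",
    "rrna": "ncRNA",
    "pseudogene": "pseudogene",
}


def _parse_gff_attributes(field: str) -> dict:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        elif " " in part:  # GTF-ish "key value"
            k, v = part.split(" ", 1)
        else:
            k, v = part, ""
        attrs[k.strip()] = urllib.parse.unquote(v.strip().strip('"'))
    return attrs


def read_gene_gff3(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Only rows with feature type ``gene`` are kept.  Attributes parsed: ID,
    Name, and biotype (``biotype`` or ``gene_biotype``); anything else is
    preserved verbatim in an ``attributes`` column.  Biotypes outside
    {protein_coding, ncRNA-like, pseudogene} map to ``other``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _source, ftype, start, end, _score, _strand, _phase, attr_field = parts
            if ftype != "gene":
                continue
            attrs = _parse_gff_attributes(attr_field)
            raw_bt = attrs.get("biotype", attrs.get("gene_biotype", "")).lower()
            rows.append(
                dict(
                    gene_id=attrs.get("ID", f"gene_{lineno}").removeprefix("gene:"),
                    gene_name=attrs.get("Name", ""),
                    chromosome=chrom,
                    start=int(start),
                    end=int(end),
                    biotype=_BIOTYPE_MAP.get(raw_bt, "other"),
                    attributes=attr_field,
                )
            )
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS + ["attributes"])
    if len(genes) and (genes["start"] > genes["end"]).any():
        raise ValueError("gene with start > end")
    return genes


def read_qtl_file(path) -> pd.DataFrame:
    """Read QTL intervals from a QTLdb-dialect GFF file or a 5-column TSV.

    The TSV form has a header line with columns chromosome, start, end,
    qtl_type, trait_name.  In the GFF dialect, trait comes from the Name
    attribute and type from a ``QTL_type``/``trait_type`` attribute (falling
    back to the feature column).
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chromosome\t"):
        qtl = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        missing = set(QTL_COLUMNS) - set(qtl.columns)
        if missing:
            raise ValueError(f"QTL TSV missing columns: {sorted(missing)}")
        return qtl[QTL_COLUMNS]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected >= 9 GFF columns")
            chrom, _src, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            attrs = _parse_gff_attributes(parts[8])
            rows.append(
                dict(
                    chromosome=chrom.removeprefix("Chr."),
                    start=int(float(start)),
                    end=int(float(end)),
                    qtl_type=attrs.get("QTL_type", attrs.get("trait_type", ftype)),
                    trait_name=attrs.get("Name", attrs.get("trait", "")),
                )
            )
    return pd.DataFrame(rows, columns=QTL_COLUMNS)


def window_lookup(
    snps: pd.DataFrame,
    features: pd.DataFrame,
    flank: int = 500_000,
    feature_kind: str = "gene",
) -> pd.DataFrame:
    """Features within ``flank`` bp of each SNP (inclusive at the boundary).

    ``snps`` needs columns snp, chrom, bp; ``features`` needs chromosome,
    start, end plus an id column (gene_id for genes; QTLs are keyed by
    interval).  Distance is 0 when the SNP lies inside the feature,
    otherwise base pairs to the nearest feature edge.  Chromosomes present
    among the SNPs but absent from the feature table are reported in
    ``result.attrs['unmatched_chromosomes']``, never silently dropped.
    """
    feats = features.copy()
    feats["chromosome"] = feats["chromosome"].astype(str)
    if feature_kind == "gene":
        feats["feature_id"] = feats["gene_id"]
    else:
        feats["feature_id"] = [
            f"{r.chromosome}:{r.start}-{r.end}:{r.qtl_type}:{r.trait_name}"
            for r in feats.itertuples()
        ]
    hits = []
    snp_chroms = set(snps["chrom"].astype(str))
    feat_chroms = set(feats["chromosome"])
    unmatched = sorted(snp_chroms - feat_chroms)
    if unmatched:
        log.warning("no %s features on chromosome(s) %s", feature_kind, unmatched)
    for chrom, snp_grp in snps.groupby(snps["chrom"].astype(str), sort=False):
        sub = feats[feats["chromosome"] == chrom]
        if sub.empty:
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        for row in snp_grp.itertuples():
            bp = int(row.bp)
            sel = (start <= bp + flank) & (end >= bp - flank)
            if not sel.any():
                continue
            dist = np.where(
                (start[sel] <= bp) & (bp <= end[sel]),
                0,
                np.minimum(np.abs(start[sel] - bp), np.abs(end[sel] - bp)),
            )
            for fid, dd, frow in zip(
                sub.loc[sel, "feature_id"], dist, sub[sel].itertuples()
            ):
                hit = dict(
                    snp=row.snp,
                    feature_id=fid,
                    feature_kind=feature_kind,
                    chromosome=chrom,
                    distance=int(dd),
                )
                if feature_kind == "qtl":
                    hit.update(
                        start=frow.start, end=frow.end,
                        qtl_type=frow.qtl_type, trait_name=frow.trait_name,
                    )
                else:
                    hit.update(gene_name=frow.gene_name, biotype=frow.biotype)
                hits.append(hit)
    out = pd.DataFrame(hits)
    if out.empty:
        cols = ["snp", "feature_id", "feature_kind", "chromosome", "distance"]
        cols += (
            ["start", "end", "qtl_type", "trait_name"]
            if feature_kind == "qtl"
            else ["gene_name", "biotype"]
        )
        out = pd.DataFrame(columns=cols)
    out.attrs["unmatched_chromosomes"] = unmatched
    return out


def qtl_type_summary(qtl_hits: pd.DataFrame) -> pd.DataFrame:
    """Distinct-QTL counts and proportions by type.

    Each distinct QTL interval (chromosome, start, end, type, trait) is
    counted once no matter how many SNPs it matched; proportions sum to 1.
    Empty input yields an empty summary.
    """
    if qtl_hits.empty:
        return pd.DataFrame(columns=["qtl_type", "n_qtl", "proportion"])
    distinct = qtl_hits.drop_duplicates(subset=QTL_KEY)
    counts = distinct.groupby("qtl_type").size().sort_values(ascending=False)
    out = counts.rename("n_qtl").reset_index()
    out["proportion"] = out["n_qtl"] / out["n_qtl"].sum()
    return out


def hypergeometric_qtl_enrichment(
    qtl_hits: pd.DataFrame, background: pd.DataFrame
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of hit QTL types vs background.

    For type t with K background QTL out of M total, and k hits out of N
    drawn, p = P[X >= k], X ~ Hypergeom(M, K, N).  Types observed among the
    hits but absent from the background are rejected.
    """
    bg = background.drop_duplicates(subset=QTL_KEY)
    bg_counts = bg.groupby("qtl_type").size()
    M = int(bg_counts.sum())
    if qtl_hits.empty:
        return pd.DataFrame(columns=["qtl_type", "n_hits", "n_background", "p_value"])
    distinct = qtl_hits.drop_duplicates(subset=QTL_KEY)
    hit_counts = distinct.groupby("qtl_type").size()
    missing = set(hit_counts.index) - set(bg_counts.index)
    if missing:
        raise ValueError(f"QTL type(s) absent from background: {sorted(missing)}")
    N = int(hit_counts.sum())
    rows = []
    for qtype, k in hit_counts.items():
        K = int(bg_counts[qtype])
        if k > K:
            raise ValueError(f"more hits than background QTL for type {qtype!r}")
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(dict(qtl_type=qtype, n_hits=int(k), n_background=K, p_value=p))
    return pd.DataFrame(rows).sort_values("p_value", ignore_index=True)
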