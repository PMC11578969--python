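"""End-to-end orchestration: simulate -> phenotype -> GWAS -> annotate.

Each stage is also usable on its own (see the analysis/ drivers and the
CLI); ``run_pipeline`` wires them together, writes every table as TSV under
a run directory, and records a manifest with the seed, a config hash and
per-stage row counts.  Reruns with the same config and seed are
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, io
from .gwas import (
    build_threshold_set,
    classify_hits,
    genomic_inflation,
    ld_prune,
    loco_grms,
    mlma_loco_scan,
    qq_table,
)
from .phenotypes import INDICATOR_COLUMNS, HSConfig, derive_all_indicators
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger(__name__)

#: chromosome field for genome-wide rows of the thresholds table
NA_ALL = "all"


@dataclass
class GwasConfig:
    fixed_effects: tuple[str, ...] = ("parity", "ventilation")
    maf_min: float = 0.01
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.1
    ne: int = 60
    indicators: tuple[str, ...] = tuple(INDICATOR_COLUMNS)


@dataclass
class AnnotationConfig:
    flank: int = 500_000
    gene_gff3: str | None = None
    qtl_file: str | None = None
    significance_level: str = "sig_suggestive"


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    hs: HSConfig = field(default_factory=HSConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # one seed drives every stochastic stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if "hs" in raw:
            kwargs["hs"] = HSConfig(**raw["hs"])
        if "gwas" in raw:
            g = dict(raw["gwas"])
            for key in ("fixed_effects", "indicators"):
                if key in g:
                    g[key] = tuple(g[key])
            kwargs["gwas"] = GwasConfig(**g)
        if "annotation" in raw:
            kwargs["annotation"] = AnnotationConfig(**raw["annotation"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if seed is not None:
            kwargs["seed"] = int(seed)
        if "log_level" in raw:
            kwargs["log_level"] = raw["log_level"]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def design_matrix(pheno: pd.DataFrame, fixed_effects=("parity", "ventilation")) -> np.ndarray:
    """Intercept plus dummy-coded class effects from the covariate columns."""
    cols = [np.ones(len(pheno))]
    for eff in fixed_effects:
        dummies = pd.get_dummies(pheno[eff].astype("category"), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def maf_filter(genotypes, maf_min: float):
    """Drop SNPs below the minor-allele-frequency cutoff."""
    from .gwas import minor_allele_frequency
    from .simulate import GenotypeMatrix

    freq = np.nanmean(genotypes.dosage, axis=0) / 2.0
    keep = minor_allele_frequency(freq) >= maf_min
    if keep.all():
        return genotypes
    sm = genotypes.snp_map.loc[keep].reset_index(drop=True)
    return GenotypeMatrix(
        dosage=genotypes.dosage[:, keep], snp_map=sm, animal_ids=genotypes.animal_ids
    )


def run_gwas_stage(pheno: pd.DataFrame, genotypes, cfg: GwasConfig):
    """Prune, build thresholds and LOCO GRMs, scan every indicator.

    Returns (per-indicator association tables with significance labels,
    thresholds, per-indicator inflation results).
    """
    genotypes = maf_filter(genotypes, cfg.maf_min)
    pruned = ld_prune(genotypes, cfg.prune_window, cfg.prune_step, cfg.prune_r2)
    thresholds = build_threshold_set(genotypes, n_pruned=len(pruned), ne=cfg.ne)
    log.info("%d SNPs after MAF filter; %d after LD pruning", genotypes.n_snps, len(pruned))
    grms = loco_grms(genotypes)
    pheno = pheno.loc[list(genotypes.animal_ids)]
    X = design_matrix(pheno, cfg.fixed_effects)

    scans, inflation = {}, {}
    for ind in cfg.indicators:
        y = pheno[ind].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if not ok.all():
            raise ValueError(
                f"{ind}: {np.sum(~ok)} missing phenotype values; "
                "drop those animals before the scan"
            )
        assoc = mlma_loco_scan(y, X, genotypes, grms=grms)
        assoc = classify_hits(assoc, thresholds)
        scans[ind] = assoc
        inflation[ind] = genomic_inflation(assoc["chi2"].dropna().to_numpy())
    return scans, thresholds, inflation


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        rec = stage("simulate")
        genotypes, truth, env, tv = simulate_cohort(config.sim)
        io.write_plink_text(genotypes, out / "genotypes")
        io.write_tv_tsv(tv, out / "tv_series.tsv")
        io.write_covariates_tsv(tv, out / "covariates.tsv")
        io.write_environment_tsv(env, out / "environment.tsv")
        io.write_truth_tsv(truth, genotypes.animal_ids, out / "truth.tsv")
        rec.update(
            n_animals=genotypes.n_animals,
            n_snps=genotypes.n_snps,
            n_tv_records=int(sum(len(s) for s in tv)),
            realized_h2=truth.realized_h2,
        )

        rec = stage("phenotype")
        pheno = derive_all_indicators(tv, config.hs)
        io.write_table(pheno, out / "cr_indicators.tsv", index=True)
        rec.update(n_animals=len(pheno), n_missing=int(pheno[list(INDICATOR_COLUMNS)].isna().sum().sum()))

        rec = stage("gwas")
        scans, thresholds, inflation = run_gwas_stage(pheno, genotypes, config.gwas)
        for ind, assoc in scans.items():
            io.write_table(assoc, out / f"assoc_{ind}.tsv")
            io.write_table(qq_table(assoc["p"].dropna().to_numpy()), out / f"qq_{ind}.tsv")
        thr_rows = [
            dict(level="bonferroni", chromosome=NA_ALL, threshold=thresholds.bonferroni),
            dict(level="suggestive", chromosome=NA_ALL, threshold=thresholds.suggestive),
        ] + [
            dict(level="chromosome_wise", chromosome=c, threshold=t)
            for c, t in thresholds.chromosome_wise.items()
        ]
        io.write_table(pd.DataFrame(thr_rows), out / "thresholds.tsv")
        io.write_table(
            pd.DataFrame(
                [
                    dict(indicator=ind, **{"lambda": r.lam}, ci_low=r.ci95[0], ci_high=r.ci95[1])
                    for ind, r in inflation.items()
                ]
            ),
            out / "lambda.tsv",
        )
        rec.update(
            n_independent_snps=thresholds.n_independent_snps,
            indicators=list(scans),
            n_indicator_scans=len(scans),
        )

        rec = stage("annotate")
        ann = config.annotation
        if ann.gene_gff3 is None and ann.qtl_file is None:
            rec["skipped"] = "no annotation files configured"
            log.info("annotation stage skipped: no feature files configured")
        else:
            sig = pd.concat(
                [
                    assoc.loc[assoc[ann.significance_level], ["snp", "chrom", "bp"]]
                    for assoc in scans.values()
                ],
                ignore_index=True,
            ).drop_duplicates(subset="snp")
            rec["n_significant_snps"] = len(sig)
            if ann.gene_gff3 is not None:
                genes = annotate.read_gene_gff3(ann.gene_gff3)
                hits = annotate.window_lookup(sig, genes, ann.flank, "gene")
                io.write_table(hits, out / "gene_hits.tsv")
                rec["n_gene_hits"] = len(hits)
            if ann.qtl_file is not None:
                qtl = annotate.read_qtl_file(ann.qtl_file)
                qhits = annotate.window_lookup(sig, qtl, ann.flank, "qtl")
                io.write_table(qhits, out / "qtl_hits.tsv")
                summary = annotate.qtl_type_summary(qhits)
                io.write_table(summary, out / "qtl_type_summary.tsv")
                if len(summary):
                    enrich = annotate.hypergeometric_qtl_enrichment(qhits, qtl)
                    io.write_table(enrich, out / "qtl_enrichment.tsv")
                rec["n_qtl_hits"] = len(qhits)
    except Exception as exc:  # noqa: BLE001 - annotate which stage failed
        last = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        manifest["stages"].setdefault(last, {})["error"] = str(exc)
        manifest["status"] = f"failed at stage {last}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {last!r} failed: {exc}") from exc

    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
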