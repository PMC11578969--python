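"""Mixed-linear-model association (MLMA) with leave-one-chromosome-out GRMs.

The scan fits, for each SNP, y = X b + x beta + epsilon with
cov(epsilon) = sigma2_g * G_(-c) + sigma2_e * I, where G_(-c) is the genomic
relationship matrix built from all chromosomes except the tested SNP's
(LOCO).  Variance components are estimated once per chromosome by REML on
the null model (no SNP) via eigendecomposition of the GRM and a bounded 1-D
search over the heritability; the variance ratio is then held fixed across
that chromosome's SNPs while the residual scale is re-estimated per SNP from
the GLS residuals, so the scan degenerates exactly to OLS when sigma2_g = 0.

Also provided: GCTA-style GRM construction, greedy windowed LD pruning,
genome-wide/suggestive/chromosome-wise significance thresholds, the genomic
inflation factor with a distribution-free 95% CI, and Q-Q plot coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeMatrix

log = logging.getLogger(__name__)

#: median of the 1-df chi-squared distribution
CHI2_1_MEDIAN = float(stats.chi2.median(df=1))


@dataclass
class GRMatrix:
    """Genomic relationship matrix, optionally excluding one chromosome."""

    values: np.ndarray
    excluded_chromosome: object = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric (tol 1e-10)")
        if np.any(np.diag(v) <= 0):
            raise ValueError("GRM diagonal entries must be positive")


@dataclass
class VarianceComponents:
    """REML estimates of the null mixed model y = Xb + u + e."""

    sigma2_g: float
    sigma2_e: float
    loglik: float
    boundary: bool = False  # optimizer hit h2 ~ 0 or ~ 1

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    @property
    def delta(self) -> float:
        """Variance ratio sigma2_g / sigma2_e."""
        return self.sigma2_g / self.sigma2_e if self.sigma2_e > 0 else np.inf


@dataclass
class ThresholdSet:
    """The three significance-threshold schemes."""

    n_independent_snps: int
    bonferroni: float
    suggestive: float
    chromosome_wise: dict

    def __post_init__(self) -> None:
        if not (0 < self.bonferroni < self.suggestive <= 1):
            raise ValueError("need 0 < bonferroni < suggestive <= 1")


@dataclass
class InflationResult:
    """Genomic inflation factor lambda with a 95% CI for the median ratio."""

    lam: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (self.ci95[0] <= self.lam <= self.ci95[1]):
            raise ValueError("ci95 must contain lambda")


# ---------------------------------------------------------------------------
# dosage helpers


def _imputed_dosage(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages; return (matrix, allele frequencies)."""
    freq = np.nanmean(dosage, axis=0) / 2.0
    x = np.where(np.isnan(dosage), 2.0 * freq, dosage)
    return x, freq


def minor_allele_frequency(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    genotypes: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``window_snps`` SNPs per chromosome, while any
    retained pair has squared dosage correlation above ``r2_max``, the
    member with the lower minor allele frequency is removed (ties: the later
    map position).  The window slides by ``step_snps``.  Monomorphic SNPs
    are dropped before pruning.  Returns retained SNP ids in map order.
    """
    x, freq = _imputed_dosage(genotypes.dosage)
    maf = minor_allele_frequency(freq)
    poly = np.nanstd(x, axis=0) > 0
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("removed %d monomorphic SNPs before LD pruning", n_mono)

    keep = poly.copy()
    snp_map = genotypes.snp_map
    for _, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while True:
            window = idx[start : start + window_snps]
            window = window[keep[window]]
            if len(window) > 1:
                sub = x[:, window]
                with np.errstate(invalid="ignore"):
                    r2 = np.corrcoef(sub, rowvar=False) ** 2
                np.fill_diagonal(r2, 0.0)
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    # drop the lower-MAF member; ties -> later position
                    gi, gj = window[i], window[j]
                    if maf[gi] < maf[gj] or (maf[gi] == maf[gj] and gi > gj):
                        drop = i
                    else:
                        drop = j
                    keep[window[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return snp_map.loc[keep, "snp"].tolist()


# ---------------------------------------------------------------------------
# GRM


def compute_grm(genotypes: GenotypeMatrix, exclude_chromosome=None) -> GRMatrix:
    """GCTA-standard GRM: G = Z Z' / m over standardized dosages.

    z_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) with p_j the sample allele
    frequency; missing dosages are replaced by 2 p_j (standardized zero).
    Monomorphic SNPs are excluded from m.
    """
    mask = np.ones(genotypes.n_snps, dtype=bool)
    if exclude_chromosome is not None:
        mask &= (genotypes.snp_map["chrom"] != exclude_chromosome).to_numpy()
    x, freq = _imputed_dosage(genotypes.dosage)
    poly = (freq > 0) & (freq < 1)
    mask &= poly
    m = int(mask.sum())
    if m < 2:
        raise ValueError(
            f"fewer than 2 polymorphic SNPs remain (excluding chromosome {exclude_chromosome!r})"
        )
    p = freq[mask]
    z = (x[:, mask] - 2 * p) / np.sqrt(2 * p * (1 - p))
    return GRMatrix(values=z @ z.T / m, excluded_chromosome=exclude_chromosome)


# ---------------------------------------------------------------------------
# REML


def _reml_profile(h2: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> tuple[float, float]:
    """Profiled restricted log-likelihood at a given h2 (constants dropped).

    ``d`` are GRM eigenvalues; ``yt``/``xt`` the rotated response/design.
    Returns (restricted loglik, profiled sigma2_e).
    """
    n, p = xt.shape
    delta = h2 / (1.0 - h2)
    w = 1.0 / (delta * d + 1.0)  # V = sigma2_e * diag(1/w) in rotated basis
    xtw = xt * w[:, None]
    xtx = xt.T @ xtw
    beta = np.linalg.solve(xtx, xtw.T @ yt)
    r = yt - xt @ beta
    rss = float(np.sum(w * r * r))
    sigma2_e = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0 or sigma2_e <= 0:
        return -np.inf, sigma2_e
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2_e)
        + np.sum(np.log(delta * d + 1.0))
        + logdet_xtx
        + (n - p)
    )
    return float(ll), sigma2_e


def reml_null(
    y: np.ndarray,
    X: np.ndarray,
    G: GRMatrix,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    h2_bounds: tuple[float, float] = (1e-6, 1 - 1e-6),
) -> VarianceComponents:
    """REML variance components of y = Xb + u + e with var(u) = G sigma2_g.

    Works in the eigenbasis of G (eigendecomposition reusable via ``eig``)
    and maximizes the restricted likelihood over the heritability with a
    bounded deterministic 1-D search (tolerance 1e-8).  Boundary solutions
    (h2 -> 0 or 1) are flagged.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("design matrix row count does not match phenotype")
    p = np.linalg.matrix_rank(X)
    if n < p + 2:
        raise ValueError("need n >= rank(X) + 2 observations")
    if eig is None:
        d, u = np.linalg.eigh(G.values)
    else:
        d, u = eig
    d = np.maximum(d, 0.0)  # numerical PSD guard
    yt = u.T @ y
    xt = u.T @ X

    res = optimize.minimize_scalar(
        lambda h2: -_reml_profile(h2, d, yt, xt)[0],
        bounds=h2_bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    ll, sigma2_e = _reml_profile(h2, d, yt, xt)
    delta = h2 / (1.0 - h2)
    boundary = h2 <= h2_bounds[0] * 10 or h2 >= 1 - (1 - h2_bounds[1]) * 10
    if boundary:
        log.debug("REML boundary solution: h2 = %.3g", h2)
    return VarianceComponents(
        sigma2_g=delta * sigma2_e, sigma2_e=sigma2_e, loglik=ll, boundary=boundary
    )


# ---------------------------------------------------------------------------
# association scan


def loco_grms(genotypes: GenotypeMatrix) -> dict:
    """One GRM per chromosome, each excluding that chromosome."""
    return {
        chrom: compute_grm(genotypes, exclude_chromosome=chrom)
        for chrom in genotypes.snp_map["chrom"].unique()
    }


def mlma_loco_scan(
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix,
    grms: dict | None = None,
    variance_components: dict | None = None,
) -> pd.DataFrame:
    """Per-SNP mixed-model association with LOCO covariance.

    For every SNP on chromosome c the model y = Xb + x beta + eps is fitted
    by GLS with cov(eps) proportional to G_(-c) * delta + I, delta fixed at
    the chromosome's null REML estimate (overridable via
    ``variance_components``) and the residual scale re-estimated per SNP
    (n - p - 1 dof).  Wald chi2 = (beta/se)^2; p from the 1-df chi-squared
    upper tail.  SNPs with zero dosage variance after imputation yield
    records with missing statistics.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n = len(y)
    if grms is None:
        grms = loco_grms(genotypes)
    x_all, freq = _imputed_dosage(genotypes.dosage)
    p_fixed = X.shape[1]

    records = []
    fitted_vc = {}
    for chrom, grp in genotypes.snp_map.groupby("chrom", sort=False):
        G = grms[chrom]
        d, u = np.linalg.eigh(G.values)
        d = np.maximum(d, 0.0)
        if variance_components is not None and chrom in variance_components:
            vc = variance_components[chrom]
        else:
            vc = reml_null(y, X, G, eig=(d, u))
        fitted_vc[chrom] = vc
        delta = vc.delta
        w = 1.0 / np.sqrt(delta * d + 1.0)
        # whitening transform (up to the residual scale)
        yt = w * (u.T @ y)
        xt = w[:, None] * (u.T @ X)
        q, _ = np.linalg.qr(xt)
        yr = yt - q @ (q.T @ yt)

        idx = grp.index.to_numpy()
        st = w[:, None] * (u.T @ x_all[:, idx])
        sr = st - q @ (q.T @ st)
        ss = np.einsum("ij,ij->j", sr, sr)
        dof = n - p_fixed - 1
        for k, gi in enumerate(idx):
            snp = grp.loc[gi]
            if ss[k] <= 1e-12 or np.isclose(np.nanstd(x_all[:, gi]), 0.0):
                records.append(
                    dict(snp=snp["snp"], chrom=chrom, bp=snp["bp"], freq=freq[gi],
                         beta=np.nan, se=np.nan, chi2=np.nan, p=np.nan)
                )
                continue
            beta = float(sr[:, k] @ yr / ss[k])
            resid = yr - beta * sr[:, k]
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(sigma2 / ss[k])
            chi2 = (beta / se) ** 2
            records.append(
                dict(
                    snp=snp["snp"], chrom=chrom, bp=snp["bp"], freq=freq[gi],
                    beta=beta, se=se, chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)),
                )
            )
    out = pd.DataFrame.from_records(records)
    out.attrs["variance_components"] = fitted_vc
    return out


# ---------------------------------------------------------------------------
# inflation, thresholds, labels, QQ


def genomic_inflation(values: np.ndarray, kind: str = "chi2") -> InflationResult:
    """Genomic inflation factor lambda with a distribution-free 95% CI.

    lambda = median(observed chi2) / median(chi2_1).  ``kind='p'`` converts
    p-values to 1-df chi-squared quantiles first.  The CI maps the
    order-statistic (binomial-rank) confidence interval for the sample
    median through the same ratio.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("empty input")
    if kind == "p":
        v = stats.chi2.isf(v, df=1)
    elif kind != "chi2":
        raise ValueError("kind must be 'chi2' or 'p'")
    if len(v) < 100:
        warnings.warn(f"only {len(v)} tests; lambda is unstable below ~100", stacklevel=2)
    n = len(v)
    lam = float(np.median(v)) / CHI2_1_MEDIAN
    s = np.sort(v)
    lo_rank = int(stats.binom.ppf(0.025, n, 0.5))
    hi_rank = int(stats.binom.ppf(0.975, n, 0.5))
    lo = s[max(lo_rank - 1, 0)] / CHI2_1_MEDIAN
    hi = s[min(hi_rank, n - 1)] / CHI2_1_MEDIAN
    lo, hi = min(lo, lam), max(hi, lam)
    return InflationResult(lam=lam, ci95=(lo, hi))


def significance_thresholds(n_pruned: int) -> tuple[float, float]:
    """Genome-wide (0.05/N) and suggestive (1/N) thresholds from the number
    of LD-independent SNPs."""
    if n_pruned < 1:
        raise ValueError("need at least one independent SNP")
    return 0.05 / n_pruned, 1.0 / n_pruned


def chromosome_wise_threshold(lengths_cm: dict, ne: int = 60) -> dict:
    """Per-chromosome 0.05/Me thresholds via the effective number of
    independent chromosomal segments.

    Me = 2 Ne L / ln(Ne L) with L the chromosome length in cM (1 cM taken
    as 1 Mb); natural log assumed.
    """
    out = {}
    for chrom, L in lengths_cm.items():
        if L <= 0:
            raise ValueError(f"chromosome {chrom!r}: length must be positive")
        nel = ne * L
        if nel <= 1:
            raise ValueError(f"chromosome {chrom!r}: Ne*L = {nel} <= 1, Me undefined")
        me = 2.0 * nel / np.log(nel)
        out[chrom] = 0.05 / me
    return out


def build_threshold_set(genotypes: GenotypeMatrix, n_pruned: int, ne: int = 60) -> ThresholdSet:
    bonf, sugg = significance_thresholds(n_pruned)
    chrom_wise = chromosome_wise_threshold(genotypes.chromosome_lengths_cm(), ne=ne)
    return ThresholdSet(
        n_independent_snps=n_pruned,
        bonferroni=bonf,
        suggestive=sugg,
        chromosome_wise=chrom_wise,
    )


def classify_hits(assoc: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Label each SNP with every significance level it reaches (p <= cutoff,
    inclusive).  Passing Bonferroni implies passing suggestive."""
    out = assoc.copy()
    p = out["p"].to_numpy()
    out["sig_bonferroni"] = p <= thresholds.bonferroni
    out["sig_suggestive"] = p <= thresholds.suggestive
    chrom_cut = out["chrom"].map(thresholds.chromosome_wise).to_numpy(dtype=float)
    out["sig_chromosome_wise"] = p <= chrom_cut
    for col in ("sig_bonferroni", "sig_suggestive", "sig_chromosome_wise"):
        out[col] = out[col].fillna(False).astype(bool)
    return out


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10(p) coordinates for a Q-Q plot.

    Expected quantiles are -log10((i - 0.5)/n) for the sorted observed
    p-values.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("empty input")
    n = len(p)
    obs = np.sort(-np.log10(p))
    exp = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))
    return pd.DataFrame({"expected": exp, "observed": obs})
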