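"""GWAS core tests: GRM standardization, REML recovery, the LOCO scan
against an explicit-inverse GLS oracle, pruning, thresholds, inflation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crgwas.gwas import (
    CHI2_1_MEDIAN,
    GRMatrix,
    VarianceComponents,
    chromosome_wise_threshold,
    classify_hits,
    compute_grm,
    genomic_inflation,
    ld_prune,
    loco_grms,
    mlma_loco_scan,
    qq_table,
    reml_null,
    significance_thresholds,
    build_threshold_set,
)
from crgwas.simulate import GenotypeMatrix, SimConfig, simulate_genotypes


def geno_from_matrix(dosage, chrom=None, bp=None):
    n, m = dosage.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    bp = np.arange(1, m + 1) * 1000 if bp is None else np.asarray(bp)
    sm = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": chrom, "bp": bp,
         "a1": "A", "a2": "B"}
    )
    return GenotypeMatrix(dosage=np.asarray(dosage, float), snp_map=sm,
                          animal_ids=[f"id{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# explicit-inverse GLS oracle (no shared code with the scan)


def gls_oracle(y, X, x_snp, G, delta):
    """Direct-solve GLS with V0 = delta*G + I and re-estimated scale."""
    n = len(y)
    V0 = delta * G + np.eye(n)
    Vi = np.linalg.inv(V0)
    W = np.column_stack([X, x_snp])
    A = np.linalg.inv(W.T @ Vi @ W)
    b = A @ W.T @ Vi @ y
    r = y - W @ b
    sigma2 = float(r @ Vi @ r) / (n - W.shape[1])
    se = np.sqrt(sigma2 * A[-1, -1])
    beta = b[-1]
    chi2 = (beta / se) ** 2
    return beta, se, chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# LD pruning


def test_duplicate_columns_pruned_to_one(rng):
    col = rng.binomial(2, 0.3, size=100).astype(float)
    other = rng.binomial(2, 0.4, size=100).astype(float)
    g = geno_from_matrix(np.column_stack([col, col, other]))
    kept = ld_prune(g)
    assert sum(s in kept for s in ("s0", "s1")) == 1
    assert "s2" in kept


def test_independent_snps_all_retained():
    cfg = SimConfig(n_animals=2000, n_chromosomes=1, snps_per_chromosome=40,
                    maf_range=(0.2, 0.5), seed=4)
    g = simulate_genotypes(cfg)
    kept = ld_prune(g)
    assert len(kept) == g.n_snps  # independent SNPs at n=2000: all r2 < 0.1


def test_vacuous_r2_threshold_keeps_all_polymorphic(rng):
    dosage = rng.binomial(2, 0.3, size=(50, 10)).astype(float)
    dosage[:, 3] = 0.0  # monomorphic
    g = geno_from_matrix(dosage)
    kept = ld_prune(g, r2_max=1.0)
    assert "s3" not in kept
    assert len(kept) == 9


# ---------------------------------------------------------------------------
# GRM


def test_grm_duplicate_genotypes_share_relationship(rng):
    dosage = rng.binomial(2, 0.3, size=(5, 200)).astype(float)
    dosage[1] = dosage[0]
    g = geno_from_matrix(dosage)
    G = compute_grm(g).values
    assert G[0, 1] == pytest.approx(G[0, 0])
    assert G[0, 1] == pytest.approx(G[1, 1])


def test_grm_mean_diagonal_near_one():
    cfg = SimConfig(n_animals=200, n_chromosomes=3, snps_per_chromosome=1000,
                    maf_range=(0.1, 0.5), seed=8)
    g = simulate_genotypes(cfg)
    G = compute_grm(g).values
    assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)
    assert np.allclose(G, G.T, atol=1e-10)


def test_grm_loco_equals_grm_on_reduced_map():
    cfg = SimConfig(n_animals=60, n_chromosomes=3, snps_per_chromosome=40, seed=5)
    g = simulate_genotypes(cfg)
    keep = (g.snp_map["chrom"] != 2).to_numpy()
    reduced = GenotypeMatrix(
        dosage=g.dosage[:, keep],
        snp_map=g.snp_map.loc[keep].reset_index(drop=True),
        animal_ids=g.animal_ids,
    )
    G_loco = compute_grm(g, exclude_chromosome=2).values
    G_red = compute_grm(reduced).values
    assert np.allclose(G_loco, G_red, atol=1e-12)


def test_grm_requires_snps_outside_excluded_chromosome(rng):
    dosage = rng.binomial(2, 0.3, size=(10, 5)).astype(float)
    g = geno_from_matrix(dosage)  # single chromosome
    with pytest.raises(ValueError, match="fewer than 2 polymorphic"):
        compute_grm(g, exclude_chromosome=1)


# ---------------------------------------------------------------------------
# REML


def test_reml_null_phenotype_h2_near_zero():
    cfg = SimConfig(n_animals=500, n_chromosomes=2, snps_per_chromosome=250, seed=2)
    g = simulate_genotypes(cfg)
    G = compute_grm(g)
    rng = np.random.default_rng(77)
    X = np.ones((500, 1))
    h2 = [reml_null(rng.normal(size=500), X, G).h2 for _ in range(10)]
    assert np.median(h2) < 0.1


def test_reml_recovers_simulated_h2():
    h2s = []
    for rep in range(15):
        cfg = SimConfig(n_animals=600, n_chromosomes=2, snps_per_chromosome=400,
                        polygenic_h2=0.3, baseline_sd=1.0, seed=300 + rep)
        g = simulate_genotypes(cfg)
        from crgwas.simulate import simulate_latent_traits

        t = simulate_latent_traits(g, cfg)
        vc = reml_null(t.latent_baseline, np.ones((600, 1)), compute_grm(g))
        h2s.append(vc.h2)
    assert np.mean(h2s) == pytest.approx(0.3, abs=0.07)


def test_reml_boundary_matches_ols_restricted_likelihood(rng):
    """At sigma2_g -> 0 the restricted likelihood is the OLS one."""
    n, p = 80, 2
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
    dosage = rng.binomial(2, 0.3, size=(n, 100)).astype(float)
    G = compute_grm(geno_from_matrix(dosage))
    from crgwas.gwas import _reml_profile

    d, u = np.linalg.eigh(G.values)
    ll0, s2 = _reml_profile(1e-12, np.maximum(d, 0), u.T @ y, u.T @ X)
    # independent OLS restricted likelihood
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ b
    s2_ols = r @ r / (n - p)
    sign, logdet = np.linalg.slogdet(X.T @ X)
    ll_ols = -0.5 * ((n - p) * np.log(2 * np.pi * s2_ols) + logdet + (n - p))
    assert s2 == pytest.approx(s2_ols, rel=1e-6)
    assert ll0 == pytest.approx(ll_ols, abs=1e-4)


def test_reml_rejects_nonfinite_phenotype():
    G = GRMatrix(values=np.eye(10))
    y = np.ones(10)
    y[3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        reml_null(y, np.ones((10, 1)), G)


# ---------------------------------------------------------------------------
# the LOCO scan


def test_scan_matches_explicit_inverse_oracle():
    cfg = SimConfig(n_animals=50, n_chromosomes=2, snps_per_chromosome=15,
                    polygenic_h2=0.3, baseline_sd=1.0, seed=13)
    g = simulate_genotypes(cfg)
    from crgwas.simulate import simulate_latent_traits

    t = simulate_latent_traits(g, cfg)
    y = t.latent_baseline
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(50), rng.integers(0, 2, size=50).astype(float)])
    grms = loco_grms(g)
    assoc = mlma_loco_scan(y, X, g, grms=grms)
    vcs = assoc.attrs["variance_components"]
    freq = np.nanmean(g.dosage, axis=0) / 2.0
    x_imp = np.where(np.isnan(g.dosage), 2 * freq, g.dosage)
    for k, row in assoc.iterrows():
        if not np.isfinite(row["beta"]):
            continue
        chrom = row["chrom"]
        beta, se, chi2, p = gls_oracle(
            y, X, x_imp[:, k], grms[chrom].values, vcs[chrom].delta
        )
        assert row["beta"] == pytest.approx(beta, abs=1e-8)
        assert row["se"] == pytest.approx(se, abs=1e-8)
        assert row["p"] == pytest.approx(p, abs=1e-8)


def test_scan_with_zero_genetic_variance_reduces_to_ols(rng):
    n, m = 40, 12
    g = geno_from_matrix(rng.binomial(2, 0.4, size=(n, m)).astype(float))
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    G = compute_grm(g)
    vc0 = VarianceComponents(sigma2_g=0.0, sigma2_e=1.0, loglik=0.0)
    assoc = mlma_loco_scan(y, X, g, grms={1: G}, variance_components={1: vc0})
    for k, row in assoc.iterrows():
        x = g.dosage[:, k]
        W = np.column_stack([X, x])
        b, *_ = np.linalg.lstsq(W, y, rcond=None)
        r = y - W @ b
        s2 = r @ r / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(W.T @ W)[-1, -1])
        assert row["beta"] == pytest.approx(b[-1], abs=1e-8)
        assert row["se"] == pytest.approx(se, abs=1e-8)


def test_scan_zero_variance_snp_yields_missing_stats(rng):
    n = 30
    dosage = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
    dosage[:, 2] = 1.0  # constant
    g = geno_from_matrix(dosage)
    assoc = mlma_loco_scan(
        rng.normal(size=n), np.ones((n, 1)), g, grms={1: compute_grm(g)}
    )
    assert np.isnan(assoc.loc[2, "p"])
    assert np.isfinite(assoc.loc[0, "p"])


def test_scan_invariant_to_animal_ordering():
    cfg = SimConfig(n_animals=60, n_chromosomes=2, snps_per_chromosome=20,
                    polygenic_h2=0.3, seed=21)
    g = simulate_genotypes(cfg)
    from crgwas.simulate import simulate_latent_traits

    t = simulate_latent_traits(g, cfg)
    rng = np.random.default_rng(3)
    perm = rng.permutation(60)
    X = np.ones((60, 1))
    a1 = mlma_loco_scan(t.latent_baseline, X, g)
    g_perm = GenotypeMatrix(
        dosage=g.dosage[perm], snp_map=g.snp_map,
        animal_ids=[g.animal_ids[i] for i in perm],
    )
    a2 = mlma_loco_scan(t.latent_baseline[perm], X, g_perm)
    assert np.allclose(a1["p"], a2["p"], atol=1e-8, equal_nan=True)


# ---------------------------------------------------------------------------
# inflation factor


def test_lambda_is_one_at_the_null_median():
    chi2 = np.full(500, CHI2_1_MEDIAN)
    res = genomic_inflation(chi2)
    assert res.lam == pytest.approx(1.0)
    assert res.ci95[0] <= res.lam <= res.ci95[1]


def test_lambda_scale_equivariance(rng):
    chi2 = stats.chi2.rvs(1, size=1000, random_state=rng)
    a = genomic_inflation(chi2)
    b = genomic_inflation(2 * chi2)
    assert b.lam == pytest.approx(2 * a.lam)


def test_lambda_near_one_for_uniform_pvalues(rng):
    p = rng.uniform(size=50_000)
    res = genomic_inflation(p, kind="p")
    assert 0.98 <= res.lam <= 1.02


def test_lambda_warns_on_few_tests_and_rejects_empty():
    with pytest.warns(UserWarning, match="unstable"):
        genomic_inflation(np.full(10, CHI2_1_MEDIAN))
    with pytest.raises(ValueError, match="empty"):
        genomic_inflation(np.array([]))


# ---------------------------------------------------------------------------
# thresholds


@pytest.mark.parametrize(
    "n,bonf,sugg",
    [(100, 5e-4, 1e-2), (1, 0.05, 1.0)],
)
def test_significance_thresholds_direct_division(n, bonf, sugg):
    assert significance_thresholds(n) == (pytest.approx(bonf), pytest.approx(sugg))


def test_me_threshold_direct_evaluation():
    thr = chromosome_wise_threshold({"1": 100.0}, ne=60)
    me = 2 * 60 * 100 / np.log(60 * 100)
    assert me == pytest.approx(1379.4, abs=0.05)
    assert thr["1"] == pytest.approx(0.05 / me)
    assert thr["1"] == pytest.approx(3.62e-5, rel=5e-3)


def test_me_increases_with_chromosome_length():
    lengths = {i: float(L) for i, L in enumerate((10, 50, 100, 200))}
    thr = chromosome_wise_threshold(lengths)
    me = {k: 0.05 / v for k, v in thr.items()}
    assert sorted(me, key=me.get) == sorted(lengths, key=lengths.get)


def test_equal_lengths_equal_thresholds_and_bad_length_rejected():
    thr = chromosome_wise_threshold({"a": 80.0, "b": 80.0})
    assert thr["a"] == thr["b"]
    with pytest.raises(ValueError, match="<= 1"):
        chromosome_wise_threshold({"a": 0.01})


def test_classify_hits_inclusive_boundary_and_nesting():
    cfg = SimConfig(n_animals=30, n_chromosomes=2, snps_per_chromosome=10, seed=1)
    g = simulate_genotypes(cfg)
    ts = build_threshold_set(g, n_pruned=1000)
    assoc = pd.DataFrame(
        {
            "snp": ["a", "b", "c"],
            "chrom": [1, 1, 2],
            "bp": [1, 2, 3],
            "p": [ts.bonferroni, 1.0, ts.suggestive],
        }
    )
    out = classify_hits(assoc, ts)
    assert out.loc[0, "sig_bonferroni"] and out.loc[0, "sig_suggestive"]
    assert not out.loc[1, ["sig_bonferroni", "sig_suggestive", "sig_chromosome_wise"]].any()
    assert out.loc[2, "sig_suggestive"] and not out.loc[2, "sig_bonferroni"]
    # nesting: every Bonferroni hit is a suggestive hit
    assert (~out["sig_bonferroni"] | out["sig_suggestive"]).all()


# ---------------------------------------------------------------------------
# Q-Q coordinates


def test_qq_uniform_grid_on_diagonal():
    n = 999
    p = (np.arange(1, n + 1) - 0.5) / n
    qq = qq_table(p)
    assert np.allclose(qq["expected"], qq["observed"], atol=1e-12)


def test_qq_single_value():
    qq = qq_table(np.array([0.5]))
    assert qq["expected"].iloc[0] == pytest.approx(-np.log10(0.5))


def test_qq_inflated_statistics_rise_above_diagonal(rng):
    chi2 = 2 * stats.chi2.rvs(1, size=5000, random_state=rng)
    p = stats.chi2.sf(chi2, 1)
    qq = qq_table(p)
    upper = qq.tail(500)
    assert (upper["observed"] > upper["expected"]).mean() > 0.95
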