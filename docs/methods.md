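# Methods

This note documents the models, estimators, numerical choices and
limitations behind `crgwas`, in the order data flows through the pipeline.

## 1. Synthetic cohort generator (`crgwas.simulate`)

The generator emulates a heat-stress phenotyping trial in lactating sows:
a genotyped cohort housed in two ventilation classes, vaginal temperature
(Tv) logged every 10 minutes over several summer weeks, and barn ambient
conditions logged every 5 minutes. It exists so that every downstream stage
can be validated against known ground truth; it makes no claim to be a
demographic simulation of a pig population.

**Genotypes.** Unlinked biallelic SNPs under Hardy–Weinberg sampling:
per-SNP allele frequency uniform on `maf_range` (default 0.05–0.5), dosage
Binomial(2, p) per animal. Stored dosage counts the *realized* minor allele
(columns are flipped when the sample frequency exceeds 0.5), which makes the
PLINK write→read round trip an exact identity. Map positions are cumulative
random gaps spanning ≈100 Mb per chromosome, strictly increasing. There is
deliberately no linkage disequilibrium, pedigree or selection — the LOCO
machinery only needs exchangeable markers, and LD-pruning behaviour is
tested on explicitly constructed correlated columns instead.

**Latent traits.** Two per-animal traits drive Tv: a baseline offset (°C,
total SD 0.30) and a heat sensitivity (gain on heat load, mean 0.08 °C per
°C of heat load, SD 0.03). Each trait is the sum of planted-QTL effects
(each QTL explains `qtl_variance_fraction` of the trait variance; effect
sign random), a polygenic part (iid small normal weights on all non-QTL
SNPs, scaled to `polygenic_h2`, default 0.20) and a normal residual taking
the remaining variance. Configurations whose genetic fractions reach 1 are
rejected. Realized variance fractions are recorded in the `TruthRecord`.

**Environment.** Ambient temperature = 27 °C base + 4 °C diurnal cosine
peaking at 15:00 + a contiguous heat-wave episode (default 25 % of days,
+5 °C) + N(0, 0.8) noise, on a 5-min grid; relative humidity moves inversely
with temperature and is clipped to [0, 100] %. Heat load is
`max(0, Ta − 25 °C)`, optionally humidity-weighted — any monotone stressor
would do for testing, and this is the simplest defensible one.

**Tv series.** For animal *i* at time *t*:

```
Tv_i(t) = 39.2 + 0.02·(parity_i − 2) + 0.15·cos(2π(h−16)/24)
          + baseline_i + sensitivity_i · heatload(t) + e_i(t)
```

with AR(1) sensor noise `e` (ρ = 0.6, stationary SD 0.15 °C — values chosen
so the autocorrelation indicators are non-degenerate). Innovations are a
per-animal mixture of a standard normal and a centred exponential whose
weight tracks latent heat sensitivity (base 0.3, gain 0.2 per SD of
sensitivity): heat-sensitive animals show right-skewed excursions (rapid
spikes, slower recovery). This channel exists because skewness is
scale-invariant — with symmetric noise the Skew indicators would carry
exactly zero genetic variance and could not be calibrated. Records are
dropped completely at random (`missing_rate`, default 2 %) so the gap policy
downstream is exercised; values are clipped to a physiological band
[37, 42.5] °C with clip events logged. Parity is uniform on 2–7; ventilation
class is assigned per animal by `ventilation_split` and is the only
barn-level factor.

**Calibration.** With defaults (400 animals, 5 × 600 SNPs, 14 days), REML
heritabilities of the twelve derived indicators average 0.10–0.23 across
replicate cohorts — inside the low-to-moderate band ([0.05, 0.35]) the
generator targets. The calibration test uses the *mean* over three seeded
cohorts at n = 1000 because a single GRM-based REML estimate has sampling
SD ≈ √(2m)/n ≈ 0.08 at this scale; a single-seed band would measure noise,
not calibration.

**What passing tests do not show.** The generator has no LD, no shared barn
micro-climates beyond ventilation class, no lactation-stage trends, no
sensor drift or informative missingness. Results on it validate the
*estimators*, not the biology of any real herd.

## 2. CR indicators (`crgwas.phenotypes`)

Deviations are taken from **trailing** windows of six consecutive 10-min
observations ending at (and including) the focal point — deviation of the
newest observation from its recent expectation, the convention of the
resilience-indicator literature; a centred window is impossible with even
length. Every time point with a complete window yields a deviation
(overlapping windows, maximal data use). Windows and lag-1 pairs must be
contiguous on the nominal grid within ±2 min; sensor gaps split the series
and are never interpolated.

Estimators: LnVar uses the natural log of the n−1 sample variance; Autocor
is the Pearson correlation of consecutive deviation pairs; Skew is the
moment estimator g₁ = m₃/m₂^1.5 with n-denominator central moments.
Degenerate inputs (too few deviations, zero variance) yield NaN flagged in
the output ("NA" on disk), never −∞ or silent zeros.

Max_Tv and HSD are daily quantities; one value per animal enters GWAS as
the mean over days (configurable: mean|median|max; days without records are
omitted, not scored zero). HSD counts observations strictly above the
animal's ventilation-class threshold in grid-contiguous runs (minimum run
length 1, configurable) times the 10-min interval, bounded by 1440 min/day.
HSU_A sums Tv − threshold over observations strictly above threshold
(≥ 0); HSU_B is the analogous signed sum over the remaining observations
(≤ 0), with an absolute-value variant behind a flag — the "below" summand is
stated as a signed total deviation, and keeping the sign preserves the
monotonicity HSU_B → 0 as an animal warms. Nor_avevar/Nor_medvar min–max
normalize each animal's whole-series mean/median Tv and Tv variance over
the population and multiply them; a population of one or a zero range is an
error (normalization undefined), surfaced rather than imputed.

## 3. Mixed-model association (`crgwas.gwas`)

**GRM.** `G = Z Zᵀ/m` with `z_ij = (x_ij − 2p_j)/√(2p_j(1−p_j))`, sample
allele frequencies, missing dosages mean-imputed (standardized zero),
monomorphic SNPs excluded. LOCO: one GRM per chromosome, excluding it.

**REML.** The null model `y = Xb + u + e`, `var(u) = Gσ²g`, is profiled in
the eigenbasis of G: for heritability h², δ = h²/(1−h²), weights
`1/(δd_i+1)` give the GLS fit, the profiled σ²e and the restricted
log-likelihood; h² is maximized by bounded deterministic search on
[10⁻⁶, 1−10⁻⁶] with tolerance 10⁻⁸ (no restarts; the profile is unimodal in
practice and boundary solutions are flagged). At δ = 0 the restricted
likelihood equals the OLS one, which the tests verify.

**Scan.** Per chromosome, the variance *ratio* δ is fixed at the LOCO null
REML estimate and held across that chromosome's SNPs (common MLMA practice;
re-estimating per SNP would cost O(m) REMLs). The data are whitened by
`diag(1/√(δd_i+1))·Uᵀ` and each SNP is fitted by OLS on the whitened scale
with the residual scale re-estimated per SNP (n−p−1 dof). This choice —
ratio fixed, scale free — makes the scan collapse *exactly* to ordinary
least squares when σ²g = 0, giving a clean degenerate-case contract; with
both components fixed the SE would carry the null σ²e instead. Wald
χ² = (β̂/se)², p from the χ²₁ upper tail. Zero-variance SNPs yield records
with missing statistics rather than being dropped.

**LD pruning.** Greedy windowed pruning (window 50 SNPs, step 5,
r² > 0.1 removed) on mean-imputed dosages; within an offending pair the
lower-MAF SNP is removed (ties: later map position) — a documented rule, as
reference implementations do not publish theirs. Monomorphic SNPs are
removed first, with a log entry.

**Thresholds.** Genome-wide 0.05/N and suggestive 1/N from the pruned count
N; chromosome-wise 0.05/Me with `Me = 2·Ne·L/ln(Ne·L)`, Ne = 60, L the
chromosome length in cM under 1 cM ≡ 1 Mb (taken as max(bp)/10⁶ from the
SNP map). The log base in Me is taken as natural (flagged in output
metadata). Significance is inclusive (p ≤ threshold) at every level.

**Inflation.** λ = median(χ²)/median(χ²₁) (null median ≈ 0.4549). The 95 %
CI is the distribution-free order-statistic interval for the sample median
(binomial ranks at 0.025/0.975) mapped through the same ratio; fewer than
100 tests triggers a warning.

## 4. Annotation (`crgwas.annotate`)

A feature is a hit when its interval intersects [snp − 500 kb, snp + 500 kb]
on the same chromosome, **inclusive** at exactly the flank distance;
distance is 0 inside the feature, else base pairs to the nearest edge.
Coordinates are 1-based inclusive (PLINK/GFF convention). Chromosome-name
mismatches are reported, never silently dropped. QTL tallies count distinct
intervals (key: chromosome, start, end, type, trait) once regardless of how
many SNPs matched; per-type proportions sum to 1. Enrichment is an
upper-tail hypergeometric test of the hit composition against the distinct
background QTL table — a documented stand-in, since interval-enrichment
tools do not all publish their test construction. GFF3 parsing keeps gene
features only (ID/Name/biotype attributes; other attributes preserved
verbatim); QTL input is either the QTLdb GFF dialect or a 5-column TSV.

## 5. Problem sizes

Desk-scale study conditions used throughout the tests and the acceptance
script, chosen so the full pipeline runs in minutes on one core: default
cohort 400 animals × 5 chromosomes × 600 SNPs × 14 days; null calibration on
that scale pooled over all 12 indicator scans; planted-QTL power at n = 800,
2 × 500 SNPs, 7 recording days, 50 replicates; REML recovery at n = 800,
50 replicates; indicator-heritability calibration at n = 800–1000. The
published analytic thresholds are reproduced from the printed pruned SNP
count (N = 42,729) exactly, since they are arithmetic, not data.

## 6. Known limitations

- No LD in the generator, so pruning on simulated panels is a no-op by
  construction (pruning behaviour is unit-tested on constructed columns).
- Repeated daily records (Max_Tv, HSD) are collapsed to one value per
  animal; no repeated-records mixed model is fitted.
- The scan's fixed effects default to intercept + parity + ventilation and
  are config-driven; no principal components are added (population
  structure is fully captured by the GRM in the synthetic setting).
- Heat-stress thresholds are inputs (config), not estimated from data.
- GO/KEGG functional enrichment via external web services is out of scope;
  only positional gene/QTL annotation and the hypergeometric QTL-type test
  are implemented.
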