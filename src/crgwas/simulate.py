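"""Synthetic cohort generator: genotypes, latent genetic effects, barn
environment, and 10-minute vaginal-temperature (Tv) series with known ground
truth.

The generator emulates the study design of a heat-stress phenotyping trial in
lactating sows: ~400 genotyped animals housed under two ventilation regimes,
Tv logged every 10 minutes over several summer weeks, and barn ambient
temperature/humidity logged every 5 minutes.  Genetic architecture (planted
QTL plus a polygenic background) is configurable per latent trait so that
downstream association and variance-component machinery can be validated
against known truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import TvSeries

log = logging.getLogger(__name__)

#: physiological clipping band for simulated Tv (degC)
TV_MIN, TV_MAX = 37.0, 42.5

#: study start used for simulated timestamps (first recording day)
STUDY_START = np.datetime64("2021-06-05T00:00")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults are the package's study conditions: 400 sows, 5 chromosomes x
    600 SNPs, 14 days of 10-min Tv records, two ventilation classes, parities
    2-7, and latent-trait heritabilities chosen so that derived resilience
    indicators land in the low-to-moderate range reported for sow
    heat-stress phenotypes (roughly 0.08-0.29).
    """

    n_animals: int = 400
    n_chromosomes: int = 5
    snps_per_chromosome: int = 600
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 0
    qtl_variance_fraction: float = 0.0
    polygenic_h2: float = 0.20
    n_days: int = 14
    sampling_interval_min: int = 10
    env_interval_min: int = 5
    ventilation_split: float = 0.5
    parity_levels: tuple[int, int] = (2, 7)
    missing_rate: float = 0.02
    seed: int = 0

    # generative scale parameters (degC unless noted)
    mean_tv: float = 39.2
    baseline_sd: float = 0.30          # total sd of the latent baseline
    sensitivity_mean: float = 0.08     # degC per unit heat load
    sensitivity_sd: float = 0.03       # total sd of latent heat sensitivity
    circadian_amplitude: float = 0.15
    parity_effect: float = 0.02        # degC per parity class above minimum
    ar_rho: float = 0.6                # AR(1) coefficient of sensor noise
    ar_sd: float = 0.15                # stationary sd of sensor noise
    # animal-specific right-skew of temperature excursions (rapid spikes,
    # slower recovery), linked to latent heat sensitivity so that the Skew
    # indicators carry genetic variance
    noise_asymmetry: float = 0.3
    noise_asymmetry_gain: float = 0.2
    comfort_temp: float = 25.0         # degC; heat load = max(0, Ta - comfort)
    humidity_weight: float = 0.0       # optional RH modulation of heat load
    env_base_temp: float = 27.0
    env_amplitude: float = 4.0
    env_noise_sd: float = 0.8
    heatwave_fraction: float = 0.25    # fraction of days in heat-wave episodes
    heatwave_boost: float = 5.0        # degC added on heat-wave days
    chromosome_span_bp: int = 100_000_000

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("ventilation_split", "missing_rate", "heatwave_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.polygenic_h2 < 1.0):
            raise ValueError(f"polygenic_h2 must be in [0, 1), got {self.polygenic_h2}")
        genetic = self.polygenic_h2 + self.n_qtl * self.qtl_variance_fraction
        if genetic >= 1.0:
            raise ValueError(
                "polygenic_h2 + n_qtl * qtl_variance_fraction = "
                f"{genetic:.3f} leaves no environmental variance"
            )
        if self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ValueError("more QTL requested than SNPs simulated")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        lo_p, hi_p = self.parity_levels
        if lo_p > hi_p:
            raise ValueError("parity_levels must be (low, high) with low <= high")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix plus its SNP map.

    ``dosage`` counts copies of the minor allele (0/1/2, NaN = missing);
    ``snp_map`` has columns snp, chrom, bp, a1 (counted allele), a2.
    """

    dosage: np.ndarray
    snp_map: pd.DataFrame
    animal_ids: list[str]

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.animal_ids) != n or len(self.snp_map) != m:
            raise ValueError("genotype dimensions inconsistent with ids/map")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["bp"].is_monotonic_increasing or grp["bp"].duplicated().any():
                raise ValueError("bp must be strictly increasing within chromosome")

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of the counted allele, missing ignored."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def chromosome_lengths_cm(self) -> dict:
        """Chromosome lengths in cM under the 1 cM = 1 Mb convention."""
        return {
            chrom: grp["bp"].max() / 1e6
            for chrom, grp in self.snp_map.groupby("chrom", sort=False)
        }


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort: planted QTL and latent traits."""

    qtl_snp_ids: list[str]
    qtl_effects: np.ndarray          # n_qtl x 2 (baseline, heat sensitivity)
    latent_baseline: np.ndarray      # per-animal degC offset
    latent_heat_sensitivity: np.ndarray  # per-animal gain on heat load
    realized_h2: dict = field(default_factory=dict)

    def to_frame(self, animal_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": animal_ids,
                "latent_baseline": self.latent_baseline,
                "latent_heat_sensitivity": self.latent_heat_sensitivity,
            }
        )


@dataclass
class EnvironmentSeries:
    """Barn ambient conditions on a regular 5-minute grid."""

    timestamps: np.ndarray   # datetime64[m]
    ambient_temp: np.ndarray  # degC
    relative_humidity: np.ndarray  # percent
    heatwave_days: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if np.any(np.diff(self.timestamps.astype("datetime64[m]")) <= np.timedelta64(0, "m")):
            raise ValueError("timestamps must be strictly increasing")
        rh = self.relative_humidity
        if np.any((rh < 0) | (rh > 100)):
            raise ValueError("relative humidity must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "ambient_temp": self.ambient_temp,
                "relative_humidity": self.relative_humidity,
            }
        )


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw unlinked biallelic SNP dosages under Hardy-Weinberg sampling.

    Per-SNP allele frequencies are uniform on ``maf_range``; each animal's
    dosage is Binomial(2, p).  Columns whose realized frequency exceeds 0.5
    are flipped so that the stored dosage always counts the minor allele in
    the sample.  Base-pair positions are drawn without replacement per
    chromosome and sorted, so the map is strictly increasing.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, c, s = config.n_animals, config.n_chromosomes, config.snps_per_chromosome
    m = c * s
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    # keep the counted allele the realized minor allele
    flip = dosage.mean(axis=0) / 2.0 > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]

    chroms = np.repeat(np.arange(1, c + 1), s)
    # strictly increasing positions: cumulative random gaps spanning ~the chromosome
    max_gap = max(2 * config.chromosome_span_bp // s, 2)
    bp = np.concatenate(
        [np.cumsum(rng.integers(1, max_gap, size=s)) for _ in range(c)]
    )
    a1 = np.where(flip, "B", "A")
    a2 = np.where(flip, "A", "B")
    snp_map = pd.DataFrame(
        {
            "snp": [f"snp{ch}_{i % s + 1}" for i, ch in enumerate(chroms)],
            "chrom": chroms,
            "bp": bp,
            "a1": a1,
            "a2": a2,
        }
    )
    animal_ids = [f"sow{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, snp_map=snp_map, animal_ids=animal_ids)


# ---------------------------------------------------------------------------
# latent traits


def _architecture(
    rng: np.random.Generator,
    z: np.ndarray,
    qtl_idx: np.ndarray,
    config: SimConfig,
    total_var: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One latent trait = QTL part + polygenic part + residual.

    ``z`` is the standardized dosage matrix.  Each planted QTL explains
    ``qtl_variance_fraction`` of ``total_var``; the polygenic part (all
    non-QTL SNPs, iid small normal weights) explains ``polygenic_h2`` of it;
    the residual takes the rest.  Returns (trait values, QTL effects on the
    standardized scale, realized h2).
    """
    n, m = z.shape
    qtl_w = np.zeros(len(qtl_idx))
    g = np.zeros(n)
    if len(qtl_idx):
        qtl_w = rng.choice([-1.0, 1.0], size=len(qtl_idx)) * np.sqrt(
            config.qtl_variance_fraction * total_var
        )
        g += z[:, qtl_idx] @ qtl_w
    poly_idx = np.setdiff1d(np.arange(m), qtl_idx)
    if config.polygenic_h2 > 0 and len(poly_idx):
        w = rng.normal(0.0, np.sqrt(config.polygenic_h2 * total_var / len(poly_idx)), size=len(poly_idx))
        g += z[:, poly_idx] @ w
    env_var = total_var * (1.0 - config.polygenic_h2 - len(qtl_idx) * config.qtl_variance_fraction)
    e = rng.normal(0.0, np.sqrt(env_var), size=n) if env_var > 0 else np.zeros(n)
    trait = g + e
    denom = np.var(trait)
    realized = float(np.var(g) / denom) if denom > 0 else 0.0
    return trait, qtl_w, realized


def simulate_latent_traits(
    genotypes: GenotypeMatrix, config: SimConfig, rng: np.random.Generator | None = None
) -> TruthRecord:
    """Build the two latent traits (baseline Tv offset, heat sensitivity).

    QTL positions are shared between the traits; effect sizes are drawn
    independently.  Requested variance fractions must leave non-negative
    environmental variance.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    freq = genotypes.allele_frequencies()
    poly = (freq > 0) & (freq < 1)
    sd = np.where(poly, np.sqrt(2 * freq * (1 - freq)), 1.0)
    z = (np.nan_to_num(genotypes.dosage) - 2 * freq) / sd
    z[:, ~poly] = 0.0

    m = genotypes.n_snps
    candidates = np.flatnonzero(poly)
    if config.n_qtl > len(candidates):
        raise ValueError("not enough polymorphic SNPs to plant the requested QTL")
    qtl_idx = np.sort(rng.choice(candidates, size=config.n_qtl, replace=False))

    base, w_base, h2_base = _architecture(rng, z, qtl_idx, config, config.baseline_sd**2)
    sens, w_sens, h2_sens = _architecture(rng, z, qtl_idx, config, config.sensitivity_sd**2)
    sens = sens + config.sensitivity_mean

    qtl_ids = genotypes.snp_map["snp"].iloc[qtl_idx].tolist()
    return TruthRecord(
        qtl_snp_ids=qtl_ids,
        qtl_effects=np.column_stack([w_base, w_sens]) if config.n_qtl else np.zeros((0, 2)),
        latent_baseline=base,
        latent_heat_sensitivity=sens,
        realized_h2={"baseline": h2_base, "heat_sensitivity": h2_sens},
    )


# ---------------------------------------------------------------------------
# environment


def simulate_environment(config: SimConfig, rng: np.random.Generator | None = None) -> EnvironmentSeries:
    """Sinusoidal diurnal ambient cycle plus heat-wave episodes plus noise.

    The diurnal peak sits mid-afternoon (15:00); heat-wave days form
    contiguous episodes and add a constant boost.  Relative humidity moves
    inversely with temperature, clipped to [0, 100] %.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    step = np.timedelta64(config.env_interval_min, "m")
    n_obs = config.n_days * 24 * 60 // config.env_interval_min
    ts = STUDY_START + step * np.arange(n_obs)
    hours = (ts - ts[0]) / np.timedelta64(1, "h")
    hour_of_day = hours % 24.0
    day = (hours // 24).astype(int)

    n_wave = int(round(config.heatwave_fraction * config.n_days))
    wave_days = np.array([], dtype=int)
    if n_wave > 0:
        start = int(rng.integers(0, config.n_days - n_wave + 1))
        wave_days = np.arange(start, start + n_wave)
    boost = np.where(np.isin(day, wave_days), config.heatwave_boost, 0.0)

    temp = (
        config.env_base_temp
        + config.env_amplitude * np.cos(2 * np.pi * (hour_of_day - 15.0) / 24.0)
        + boost
        + rng.normal(0.0, config.env_noise_sd, size=n_obs)
    )
    rh = np.clip(
        70.0 - 1.5 * (temp - config.env_base_temp) + rng.normal(0.0, 3.0, size=n_obs),
        0.0,
        100.0,
    )
    return EnvironmentSeries(
        timestamps=ts.astype("datetime64[m]"),
        ambient_temp=temp,
        relative_humidity=rh,
        heatwave_days=wave_days,
    )


def heat_load(env: EnvironmentSeries, config: SimConfig) -> np.ndarray:
    """Nonnegative heat load max(0, Ta - comfort), optionally RH-weighted."""
    load = np.maximum(0.0, env.ambient_temp - config.comfort_temp)
    if config.humidity_weight:
        load = load * (1.0 + config.humidity_weight * (env.relative_humidity - 50.0) / 50.0)
    return np.maximum(load, 0.0)


# ---------------------------------------------------------------------------
# vaginal-temperature series


def simulate_tv_series(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    env: EnvironmentSeries,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TvSeries]:
    """Simulate each animal's 10-min Tv series.

    Tv_i(t) = mean + parity effect + circadian term + latent baseline_i
    + latent heat sensitivity_i x heat load(t) + AR(1) sensor noise, with
    records dropped completely at random at ``missing_rate`` and values
    clipped to the physiological band [37, 42.5] degC (clip events logged).
    """
    config.validate()
    n = genotypes.n_animals
    if len(truth.latent_baseline) != n:
        raise ValueError("truth record does not match the genotyped animal set")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)

    step = np.timedelta64(config.sampling_interval_min, "m")
    per_day = 24 * 60 // config.sampling_interval_min
    n_obs = config.n_days * per_day
    ts = (STUDY_START + step * np.arange(n_obs)).astype("datetime64[m]")
    hour_of_day = ((ts - ts[0]) / np.timedelta64(1, "h")) % 24.0

    # align environment to the Tv grid (nearest 5-min record)
    env_idx = np.clip(
        np.round((ts - env.timestamps[0]) / (env.timestamps[1] - env.timestamps[0])).astype(int),
        0,
        len(env.timestamps) - 1,
    )
    load = heat_load(env, config)[env_idx]

    circadian = config.circadian_amplitude * np.cos(2 * np.pi * (hour_of_day - 16.0) / 24.0)
    parity = rng.integers(config.parity_levels[0], config.parity_levels[1] + 1, size=n)
    ventilation = np.where(
        rng.random(n) < config.ventilation_split, "mechanical", "natural"
    )
    barn = np.where(ventilation == "mechanical", "barn_M", "barn_N")

    # AR(1) noise, stationary sd = ar_sd; innovations are a per-animal
    # normal/centered-exponential mixture whose weight tracks latent heat
    # sensitivity, so excursion skewness is heritable
    innov_sd = config.ar_sd * np.sqrt(max(1.0 - config.ar_rho**2, 0.0))
    sens_scale = config.sensitivity_sd if config.sensitivity_sd > 0 else 1.0
    w_skew = np.clip(
        config.noise_asymmetry
        + config.noise_asymmetry_gain
        * (truth.latent_heat_sensitivity - config.sensitivity_mean)
        / sens_scale,
        0.0,
        0.9,
    )
    noise = np.empty((n, n_obs))
    noise[:, 0] = rng.normal(0.0, config.ar_sd, size=n) if config.ar_sd > 0 else 0.0
    if innov_sd > 0:
        z = rng.normal(0.0, 1.0, size=(n, n_obs))
        expo = rng.exponential(1.0, size=(n, n_obs)) - 1.0
        mix_sd = np.sqrt((1.0 - w_skew) ** 2 + w_skew**2)
        shocks = innov_sd * ((1.0 - w_skew)[:, None] * z + w_skew[:, None] * expo) / mix_sd[:, None]
    else:
        shocks = np.zeros((n, n_obs))
    for t in range(1, n_obs):
        noise[:, t] = config.ar_rho * noise[:, t - 1] + shocks[:, t]

    det = (
        config.mean_tv
        + config.parity_effect * (parity - config.parity_levels[0])[:, None]
        + circadian[None, :]
        + truth.latent_baseline[:, None]
        + truth.latent_heat_sensitivity[:, None] * load[None, :]
    )
    tv = det + noise
    n_clipped = int(np.sum((tv < TV_MIN) | (tv > TV_MAX)))
    if n_clipped:
        log.info("clipped %d Tv values to [%s, %s] degC", n_clipped, TV_MIN, TV_MAX)
    tv = np.clip(tv, TV_MIN, TV_MAX)

    keep = rng.random((n, n_obs)) >= config.missing_rate
    series = []
    for i, aid in enumerate(genotypes.animal_ids):
        mask = keep[i]
        series.append(
            TvSeries(
                animal_id=aid,
                timestamps=ts[mask],
                tv=tv[i, mask],
                ventilation=str(ventilation[i]),
                parity=int(parity[i]),
                barn_id=str(barn[i]),
            )
        )
    return series


def simulate_cohort(config: SimConfig):
    """Run the four generator stages with one seed lineage.

    Returns (genotypes, truth, environment, tv_series).
    """
    genotypes = simulate_genotypes(config)
    truth = simulate_latent_traits(genotypes, config)
    env = simulate_environment(config)
    tv = simulate_tv_series(genotypes, truth, env, config)
    return genotypes, truth, env, tv
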