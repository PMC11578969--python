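"""Shared fixtures: small synthetic cohorts and hand-rolled series builders."""

from __future__ import annotations

import numpy as np
import pytest

from crgwas.phenotypes import TvSeries
from crgwas.simulate import SimConfig, simulate_cohort


def make_series(
    values,
    animal_id: str = "sow0001",
    start: str = "2021-06-05T00:00",
    interval_min: int = 10,
    ventilation: str = "mechanical",
    parity: int = 3,
    drop_indices=(),
) -> TvSeries:
    """Build a TvSeries on a regular grid, optionally with holes."""
    values = np.asarray(values, dtype=float)
    ts = np.datetime64(start) + np.timedelta64(interval_min, "m") * np.arange(len(values))
    keep = np.ones(len(values), dtype=bool)
    keep[list(drop_indices)] = False
    return TvSeries(
        animal_id=animal_id,
        timestamps=ts[keep],
        tv=values[keep],
        ventilation=ventilation,
        parity=parity,
        barn_id="barn_T",
    )


def random_gappy_series(rng: np.random.Generator, n_obs: int = 60, animal_id: str = "sowR"):
    """Random Tv-like series with random sensor gaps, for oracle comparisons."""
    values = 39.0 + rng.normal(0.0, 0.5, size=n_obs)
    n_drop = int(rng.integers(0, max(n_obs // 5, 1)))
    drop = rng.choice(n_obs, size=n_drop, replace=False)
    return make_series(values, animal_id=animal_id, drop_indices=drop)


@pytest.fixture(scope="session")
def small_cohort():
    """50 animals, 2 chromosomes x 60 SNPs, 3 days — fast, genetically live."""
    cfg = SimConfig(
        n_animals=50,
        n_chromosomes=2,
        snps_per_chromosome=60,
        n_days=3,
        seed=11,
    )
    genotypes, truth, env, tv = simulate_cohort(cfg)
    return cfg, genotypes, truth, env, tv


@pytest.fixture()
def rng():
    return np.random.default_rng(20210605)
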