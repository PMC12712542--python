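"""Synthetic individual-level trait tables with realistic hierarchical structure.

The generator emulates the statistical shape of individual records in large
plant-trait compilations: lognormal variation of species means, lognormal
within-species (intraspecific) variation, unequal per-species sample sizes,
optional measurement noise, and optionally disjoint individual sets per
trait (traits measured on different individuals of the same species).

The default configuration mirrors the scale of the fine-root demonstration
dataset — 1920 individuals across 368 species — with two traits, fine-root
diameter D (mm) and root tissue density RTD (g cm^-3), at between- and
within-species spreads typical of fine-root trait compilations.

All randomness flows from a single seeded generator consumed in a fixed,
documented order (count allocation, then species loop: per-trait species
log-means, then per-trait per-individual deviations), so a given seed yields
a byte-identical table on every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .trait_data import TRAIT_COLUMNS, TraitMeasurementTable

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "ConfigError",
    "default_config",
    "simulate_trait_table",
    "simulate_coupled_traits",
]


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class TraitSpec:
    """Lognormal specification of one trait.

    ``within_log_sd`` is either a constant (homogeneous mode) or a
    ``(lo, hi)`` range (heterogeneous mode): each species' log-SD is then
    lo + (hi - lo) * percentile-rank of its latent log-mean, so species with
    larger means are also more variable — the configuration under which
    aggregation-order bias is most visible.
    """

    name: str
    between_log_mean: float = 0.0
    between_log_sd: float = 0.5
    within_log_sd: float | tuple[float, float] = 0.2

    def __post_init__(self) -> None:
        if self.between_log_sd < 0:
            raise ConfigError(f"trait {self.name!r}: between_log_sd must be >= 0")
        w = self.within_log_sd
        if isinstance(w, (tuple, list)):
            if len(w) != 2 or w[0] < 0 or w[1] < w[0]:
                raise ConfigError(
                    f"trait {self.name!r}: within_log_sd range must be (lo, hi) with 0 <= lo <= hi"
                )
        elif w < 0:
            raise ConfigError(f"trait {self.name!r}: within_log_sd must be >= 0")

    def within_sd_for(self, rank01: np.ndarray) -> np.ndarray:
        """Per-species within log-SD given percentile ranks in [0, 1]."""
        w = self.within_log_sd
        if isinstance(w, (tuple, list)):
            lo, hi = float(w[0]), float(w[1])
            return lo + (hi - lo) * rank01
        return np.full_like(rank01, float(w))


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the synthetic trait-table generator."""

    n_species: int = 368
    total_individuals: int = 1920
    traits: tuple[TraitSpec, ...] = ()
    n_per_species: tuple[int, int] = (1, 10)
    shared_individuals: bool = True
    measurement_noise_log_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.total_individuals < 1:
            raise ConfigError("n_species and total_individuals must be positive")
        lo, hi = self.n_per_species
        if lo < 1 or hi < lo:
            raise ConfigError("n_per_species must be (min, max) with 1 <= min <= max")
        if self.total_individuals < self.n_species:
            raise ConfigError(
                f"total_individuals ({self.total_individuals}) cannot cover "
                f"{self.n_species} species at >= 1 individual each"
            )
        if self.measurement_noise_log_sd < 0:
            raise ConfigError("measurement_noise_log_sd must be >= 0")
        if not self.traits:
            raise ConfigError("at least one trait spec is required")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate trait names in config: {names}")


def default_config(seed: int = 0, heterogeneous: bool = False) -> SimulationConfig:
    """Default fine-root configuration: 368 species, 1920 individuals.

    Traits are fine-root diameter D (mm) and root tissue density RTD
    (g cm^-3) with lognormal between-species spreads typical of fine-root
    compilations.  ``heterogeneous=True`` couples each species' within-
    species log-SD to its mean over the range (0.05, 0.60), which amplifies
    aggregation-order bias.
    """
    if heterogeneous:
        within_d: float | tuple[float, float] = (0.05, 0.60)
        within_rtd: float | tuple[float, float] = (0.05, 0.60)
    else:
        within_d, within_rtd = 0.15, 0.20
    return SimulationConfig(
        n_species=368,
        total_individuals=1920,
        traits=(
            TraitSpec("D", between_log_mean=math.log(0.35), between_log_sd=0.45,
                      within_log_sd=within_d),
            TraitSpec("RTD", between_log_mean=math.log(0.25), between_log_sd=0.40,
                      within_log_sd=within_rtd),
        ),
        seed=seed,
    )


def _allocate_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-species individual counts summing exactly to total_individuals.

    Raw counts are drawn uniformly from the configured range, rescaled to
    the target total, and rounded by largest remainder; every species keeps
    at least one individual.
    """
    lo, hi = config.n_per_species
    raw = rng.integers(lo, hi + 1, size=config.n_species).astype(float)
    target = raw * (config.total_individuals / raw.sum())
    base = np.maximum(1, np.floor(target).astype(int))
    deficit = config.total_individuals - int(base.sum())
    if deficit > 0:
        remainder = target - np.floor(target)
        order = np.lexsort((np.arange(config.n_species), -remainder))
        for i in order[:deficit]:
            base[i] += 1
    elif deficit < 0:
        # floor clamping overshot; trim from the largest counts
        order = np.argsort(-base, kind="stable")
        k = 0
        while deficit < 0:
            i = order[k % config.n_species]
            if base[i] > 1:
                base[i] -= 1
                deficit += 1
            k += 1
    assert int(base.sum()) == config.total_individuals
    return base


def _species_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"sp{idx + 1:0{width}d}" for idx in range(n)]


def _rank01(values: np.ndarray) -> np.ndarray:
    """Percentile rank of each value within the vector, in [0, 1]."""
    order = np.argsort(np.argsort(values))
    if values.size == 1:
        return np.full(1, 0.5)
    return order / (values.size - 1)


def simulate_trait_table(config: SimulationConfig) -> TraitMeasurementTable:
    """Draw an individual-level trait table under the configured hierarchy.

    For each species s and trait t, a latent log-mean is drawn from
    Normal(between_log_mean, between_log_sd); each individual's value is
    exp(log-mean + within-species deviation + measurement noise), hence
    strictly positive by construction.

    ``shared_individuals=False`` (exactly two traits) splits each species'
    individuals into two halves measured for the first and second trait
    respectively, the odd individual going to the first — emulating traits
    compiled from different source datasets.
    """
    if not config.shared_individuals and len(config.traits) != 2:
        raise ConfigError("disjoint individual sets require exactly two traits")
    rng = np.random.default_rng(config.seed)
    counts = _allocate_counts(config, rng)
    species = _species_ids(config.n_species)

    # latent species log-means: drawn species-by-species, trait within species
    log_means = np.empty((config.n_species, len(config.traits)))
    for s in range(config.n_species):
        for k, trait in enumerate(config.traits):
            log_means[s, k] = rng.normal(trait.between_log_mean, trait.between_log_sd)

    within_sds = np.column_stack(
        [trait.within_sd_for(_rank01(log_means[:, k]))
         for k, trait in enumerate(config.traits)]
    )

    rows: list[tuple[str, str, str, float]] = []
    for s in range(config.n_species):
        n_ind = int(counts[s])
        ind_ids = [f"{species[s]}_ind{i + 1:03d}" for i in range(n_ind)]
        for k, trait in enumerate(config.traits):
            if config.shared_individuals:
                measured = ind_ids
            else:
                half = (n_ind + 1) // 2  # odd individual goes to the first trait
                measured = ind_ids[:half] if k == 0 else ind_ids[half:]
            for ind in measured:
                dev = rng.normal(0.0, within_sds[s, k])
                noise = rng.normal(0.0, config.measurement_noise_log_sd)
                value = math.exp(log_means[s, k] + dev + noise)
                rows.append((species[s], ind, trait.name, value))
    return TraitMeasurementTable(pd.DataFrame(rows, columns=list(TRAIT_COLUMNS)))


def simulate_coupled_traits(
    config: SimulationConfig,
    a: float,
    b: float,
    coupling_noise_log_sd: float = 0.0,
    x_trait: str | None = None,
    y_trait: str = "y",
) -> TraitMeasurementTable:
    """Simulate a predictor trait x and a power-law response y = a * x^b.

    The x trait follows the first (or named) trait spec of ``config``; each
    individual's y is a * x^b, optionally perturbed by lognormal noise of
    log-SD ``coupling_noise_log_sd``.  With zero noise the individual-level
    log-log relationship ln y = ln a + b ln x is exact, so averaging logs
    preserves it exactly at the species level.

    In disjoint mode (``shared_individuals=False``) the y records are kept
    for the second half of each species' individuals and the x records for
    the first half, so the two traits share no individuals.
    """
    if a <= 0:
        raise ConfigError(f"coupling coefficient a must be > 0, got {a}")
    if not math.isfinite(b):
        raise ConfigError(f"coupling exponent b must be finite, got {b}")
    if coupling_noise_log_sd < 0:
        raise ConfigError("coupling_noise_log_sd must be >= 0")

    names = [t.name for t in config.traits]
    x_trait = x_trait or names[0]
    if x_trait not in names:
        raise ConfigError(f"x_trait {x_trait!r} not in config traits {names}")
    if y_trait in names:
        raise ConfigError(f"y_trait {y_trait!r} collides with a simulated trait")

    x_spec = config.traits[names.index(x_trait)]
    base = replace(config, traits=(x_spec,), shared_individuals=True)
    table = simulate_trait_table(base)
    df = table.df

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    x_vals = df["value"].to_numpy()
    noise = rng.normal(0.0, coupling_noise_log_sd, size=len(df)) \
        if coupling_noise_log_sd > 0 else np.zeros(len(df))
    y_vals = a * np.power(x_vals, b) * np.exp(noise)
    y_df = df.assign(trait=y_trait, value=y_vals)

    if config.shared_individuals:
        out = pd.concat([df, y_df], ignore_index=True)
    else:
        keep_x, keep_y = [], []
        for _, grp in df.groupby("species", sort=True):
            inds = sorted(grp["individual"].unique())
            half = (len(inds) + 1) // 2
            keep_x.extend(inds[:half])
            keep_y.extend(inds[half:])
        out = pd.concat(
            [df[df["individual"].isin(keep_x)], y_df[y_df["individual"].isin(keep_y)]],
            ignore_index=True,
        )
    return TraitMeasurementTable(out)
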