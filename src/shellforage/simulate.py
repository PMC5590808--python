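"""Synthetic two-island survey generator.

Generates datasets with the statistical structure the downstream analyses
assume, so every stage can be exercised and calibrated without field data:

* oyster-tool weights: sqrt(weight) = mu + island effect + per-individual
  random intercept + noise (repeated tools per tool user),
* snail-tool weights: log(weight) = mu + island effect + noise (no user
  identities),
* per-plot snail counts: Poisson (optionally negative binomial) with
  island- and species-specific means,
* prey dimensions: truncated-normal lengths/widths with an island shift,
* maturation samples: stage is a discretised monotone function of shell
  size plus noise, identical on both islands by construction.

Defaults mirror the field design of the study system: 93 oyster tools per
island from 14 vs 4 adult males, 45 vs 22 snail tools, 14 one-metre point
transects per island, 100 size records per taxon and island, and per-plot
count means equal to the observed transect totals divided by 14.

One master seed governs everything through ``numpy.random.SeedSequence``
spawning, in fixed stage order (oyster tools, snail tools, transects,
sizes, maturation), so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .domain import (
    ConsumptionRates,
    Island,
    IslandProfile,
    MaturationSample,
    SizeRecord,
    SnailTransectPlot,
    StoneMeasurement,
    StoneQuadrat,
    SurveyDataset,
    Task,
    Taxon,
    ToolUseRecord,
    Zone,
)

__all__ = ["SimulationConfig", "generate_dataset", "generate_consumption_scenario"]

ISLANDS = (Island.KORAM, Island.NOMSAO)

# observed per-plot abundance means: island transect totals / 14 plots
DEFAULT_ABUNDANCE: dict[str, dict[Taxon, float]] = {
    Island.KORAM.value: {
        Taxon.P_SULCATUS: 181 / 14,
        Taxon.C_BIFASCIATUS: 50 / 14,
        Taxon.M_LABIO: 4 / 14,
    },
    Island.NOMSAO.value: {
        Taxon.P_SULCATUS: 568 / 14,
        Taxon.C_BIFASCIATUS: 22 / 14,
        Taxon.M_LABIO: 68 / 14,
    },
}

# taxon -> (mean length mm on Koram, sd, width/length ratio)
DEFAULT_SIZE_PROFILE: dict[Taxon, tuple[float, float, float]] = {
    Taxon.OYSTER: (30.0, 6.0, 0.7),
    Taxon.P_SULCATUS: (14.0, 2.5, 0.75),
    Taxon.C_BIFASCIATUS: (18.0, 3.0, 0.55),
    Taxon.M_LABIO: (12.0, 2.5, 0.9),
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the two-island generator.

    Island effects are expressed as the shift of NomSao relative to Koram
    on the model's transformed scale (sqrt grams for oyster tools, log
    grams for snail tools, mm of shell length for prey size).
    """

    seed: int = 0
    n_tools_oyster: tuple[int, int] = (93, 93)
    n_individuals_oyster: tuple[int, int] = (14, 4)
    n_tools_snail: tuple[int, int] = (45, 22)
    n_transects: tuple[int, int] = (14, 14)
    n_size_records: int = 100
    n_maturation_per_cell: int = 5

    # oyster tools, sqrt-gram scale
    mu_oyster_sqrt: float = 8.0
    island_effect_tool_sqrt: float = 1.729
    individual_sd: float = 1.0
    noise_sd_oyster: float = 2.0

    # snail tools, log-gram scale
    mu_snail_log: float = 3.3
    island_effect_tool_log: float = 0.585
    noise_sd_snail: float = 0.6

    # prey sizes (mm of shell length)
    island_effect_size: float = 4.0
    size_profile: Mapping[Taxon, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_PROFILE)
    )

    # per-plot count means; None -> the observed defaults
    abundance_rate: Mapping[str, Mapping[Taxon, float]] | None = None
    nb_dispersion: float | None = None  # None -> Poisson counts

    # maturation: stage ~ discretised linear function of shell size
    maturation_slope: float = 0.25
    maturation_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("individual_sd", "noise_sd_oyster", "noise_sd_snail",
                     "maturation_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.maturation_slope <= 0:
            raise ConfigError("maturation_slope must be > 0")
        for pair_name in ("n_tools_oyster", "n_individuals_oyster",
                          "n_tools_snail", "n_transects"):
            pair = getattr(self, pair_name)
            if any(int(v) < 1 for v in pair):
                raise ConfigError(f"{pair_name} entries must be >= 1")
        for (n_tools, n_ind) in zip(self.n_tools_oyster, self.n_individuals_oyster):
            if n_ind > n_tools:
                raise ConfigError("more oyster-tool users than tools")

    def rates(self) -> Mapping[str, Mapping[Taxon, float]]:
        return self.abundance_rate or DEFAULT_ABUNDANCE


def _positive_normal(rng: np.random.Generator, loc, scale, size=None) -> np.ndarray:
    """Normal draws with non-positive values redrawn (slightly lifts the mean)."""
    out = rng.normal(loc, scale, size)
    arr = np.atleast_1d(np.asarray(out, dtype=float))
    for _ in range(1000):
        bad = arr <= 0
        if not bad.any():
            break
        arr[bad] = rng.normal(np.broadcast_to(loc, arr.shape)[bad]
                              if np.ndim(loc) else loc, scale, bad.sum())
    else:
        raise ConfigError("could not draw positive values; check means vs sds")
    return arr if np.ndim(out) else float(arr[0])


def _gen_oyster_tools(cfg: SimulationConfig, rng: np.random.Generator):
    tools = []
    for isl_i, island in enumerate(ISLANDS):
        n_tools = cfg.n_tools_oyster[isl_i]
        n_ind = cfg.n_individuals_oyster[isl_i]
        intercepts = rng.normal(0.0, cfg.individual_sd, n_ind)
        owners = rng.integers(0, n_ind, n_tools)
        # every individual contributes at least one tool
        owners[:n_ind] = np.arange(n_ind)
        shift = cfg.island_effect_tool_sqrt if island is Island.NOMSAO else 0.0
        mu = cfg.mu_oyster_sqrt + shift + intercepts[owners]
        sqrt_w = _positive_normal(rng, mu, cfg.noise_sd_oyster, n_tools)
        for k in range(n_tools):
            tools.append(
                ToolUseRecord(
                    island=island,
                    tool_id=f"{island.value}-oy-{k:03d}",
                    task=Task.OYSTER,
                    weight_g=float(sqrt_w[k] ** 2),
                    user_id=f"{island.value}-M{owners[k]:02d}",
                    user_class="adult_male",
                )
            )
    return tools


def _gen_snail_tools(cfg: SimulationConfig, rng: np.random.Generator):
    tools = []
    for isl_i, island in enumerate(ISLANDS):
        n = cfg.n_tools_snail[isl_i]
        shift = cfg.island_effect_tool_log if island is Island.NOMSAO else 0.0
        logw = rng.normal(cfg.mu_snail_log + shift, cfg.noise_sd_snail, n)
        for k in range(n):
            tools.append(
                ToolUseRecord(
                    island=island,
                    tool_id=f"{island.value}-sn-{k:03d}",
                    task=Task.SNAIL,
                    weight_g=float(np.exp(logw[k])),
                    user_id=None,
                    user_class="unknown",
                    provenance="cracking_site",
                )
            )
    return tools


def _gen_transects(cfg: SimulationConfig, rng: np.random.Generator):
    plots = []
    rates = cfg.rates()
    for isl_i, island in enumerate(ISLANDS):
        island_rates = rates[island.value]
        for t in range(1, cfg.n_transects[isl_i] + 1):
            counts = {}
            for sp in (Taxon.P_SULCATUS, Taxon.C_BIFASCIATUS, Taxon.M_LABIO):
                lam = float(island_rates.get(sp, 0.0))
                if cfg.nb_dispersion is None:
                    counts[sp] = int(rng.poisson(lam))
                else:
                    # NB as gamma-Poisson mixture; dispersion k -> var lam+lam^2/k
                    k = cfg.nb_dispersion
                    counts[sp] = int(rng.poisson(rng.gamma(k, lam / k))) if lam > 0 else 0
            plots.append(SnailTransectPlot(island, t, counts))
    return plots


def _gen_sizes(cfg: SimulationConfig, rng: np.random.Generator):
    records = []
    for taxon, (mean_len, sd, ratio) in cfg.size_profile.items():
        for island in ISLANDS:
            shift = cfg.island_effect_size if island is Island.NOMSAO else 0.0
            lengths = _positive_normal(rng, mean_len + shift, sd, cfg.n_size_records)
            widths = _positive_normal(rng, ratio * (mean_len + shift), sd * ratio,
                                      cfg.n_size_records)
            for L, W in zip(lengths, widths):
                records.append(
                    SizeRecord(island=island, taxon=taxon,
                               length_mm=float(L), width_mm=float(W))
                )
    return records


def _gen_maturation(cfg: SimulationConfig, rng: np.random.Generator):
    """Four field size categories per species x island; stage from size only.

    The stage map is shared across islands, so the island indicator carries
    no information about stage given size — the no-life-history-change null
    the maturation analysis is designed to detect departures from.
    """
    samples = []
    for species in (Taxon.P_SULCATUS, Taxon.C_BIFASCIATUS):
        base = cfg.size_profile[species][0]
        for island in ISLANDS:
            for cat in (1, 2, 3, 4):
                mean_size = base * (0.5 + 0.25 * cat)
                sizes = _positive_normal(rng, mean_size, 0.08 * mean_size,
                                         cfg.n_maturation_per_cell)
                latent = (1.0 + cfg.maturation_slope * (sizes - 0.75 * base)
                          + rng.normal(0, cfg.maturation_noise_sd, sizes.size))
                stages = np.clip(np.round(latent), 1, 4)
                for s, st in zip(sizes, stages):
                    samples.append(
                        MaturationSample(island=island, species=species,
                                         size_category=cat,
                                         shell_size_mm=float(s), stage=int(st))
                    )
    return samples


def _gen_stone_quadrats(cfg: SimulationConfig, rng: np.random.Generator):
    """Seven locations x two littoral zones per island, 20 x 20 cm plots.

    Emulates the observed pattern: similar candidate-stone counts on the
    two islands but lighter stones on NomSao.
    """
    quadrats = []
    mean_w = {Island.KORAM: 90.0, Island.NOMSAO: 70.0}
    for island in ISLANDS:
        for loc in range(1, 8):
            for zone in (Zone.OYSTER_BED, Zone.TIDAL):
                n = int(rng.poisson(20.0))
                weights = _positive_normal(rng, mean_w[island], 35.0, max(n, 1))[:n]
                stones = tuple(
                    StoneMeasurement(weight_g=float(w),
                                     length_mm=float(min(20 + 0.5 * w, 190.0)),
                                     width_mm=float(min(15 + 0.3 * w, 150.0)))
                    for w in weights
                )
                quadrats.append(StoneQuadrat(island, loc, zone, stones))
    return quadrats


def generate_dataset(config: SimulationConfig | None = None) -> SurveyDataset:
    """Draw a complete two-island survey dataset from the generator.

    Fully reproducible: the same ``config.seed`` yields the same dataset.
    """
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    ds = SurveyDataset(
        tools=_gen_oyster_tools(cfg, streams[0]) + _gen_snail_tools(cfg, streams[1]),
        snail_transects=_gen_transects(cfg, streams[2]),
        prey_sizes=_gen_sizes(cfg, streams[3]),
        maturation=_gen_maturation(cfg, streams[4]),
        stone_quadrats=_gen_stone_quadrats(cfg, streams[5]),
    )
    profiles, rates = generate_consumption_scenario()
    ds.profiles = {p.island: p for p in profiles}
    ds.consumption = rates
    return ds


def generate_consumption_scenario(
    *,
    shoreline_m: Mapping[str, float] | None = None,
    n_tool_users: Mapping[str, int] | None = None,
    strip_width_m: float = 3.0,
    oysters_per_day: float = 36.0,
    periwinkles_per_hour: float = 1.6,
    other_per_day: float = 8.9,
    foraging_hours_per_day: float = 4.0,
    days_per_year: int = 365,
) -> tuple[tuple[IslandProfile, IslandProfile], ConsumptionRates]:
    """Island profiles and consumption rates of the study system.

    Defaults: 1551 m of accessible shoreline and 26 tool users on Koram,
    653 m and 4 on NomSao, a 3 m foraging strip, and per-individual daily
    consumption of 36 oysters, 1.6 periwinkles per foraging hour and 8.9
    other items over 4 foraging hours, 365 days a year.
    """
    shoreline = {Island.KORAM.value: 1551.0, Island.NOMSAO.value: 653.0}
    users = {Island.KORAM.value: 26, Island.NOMSAO.value: 4}
    group = {Island.KORAM.value: 64, Island.NOMSAO.value: 9}
    area = {Island.KORAM.value: 0.45, Island.NOMSAO.value: 0.10}
    if shoreline_m:
        shoreline.update({str(k): float(v) for k, v in shoreline_m.items()})
    if n_tool_users:
        users.update({str(k): int(v) for k, v in n_tool_users.items()})
    profiles = tuple(
        IslandProfile(
            island=isl,
            n_tool_users=users[isl.value],
            accessible_shoreline_m=shoreline[isl.value],
            strip_width_m=strip_width_m,
            group_size=group[isl.value],
            area_km2=area[isl.value],
        )
        for isl in ISLANDS
    )
    rates = ConsumptionRates(
        oysters_per_day=oysters_per_day,
        periwinkles_per_hour=periwinkles_per_hour,
        other_per_day=other_per_day,
        foraging_hours_per_day=foraging_hours_per_day,
        days_per_year=days_per_year,
    )
    return profiles, rates
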