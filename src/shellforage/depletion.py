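"""Consumption-extrapolation depletion model and prey-vulnerability rules.

The depletion model asks a simple sustainability question: if the island's
tool-using monkeys keep consuming shellfish at the observed per-individual
rate, how does one year of consumption compare with the standing prey
population along the foraging shoreline?

Standing stock is estimated from point-transect densities scaled to the
foraging area (accessible shoreline x a fixed strip width); annual
consumption is extrapolated from focal-observation rates.  Replenishment is
deliberately out of model — both main prey species have planktonic larvae,
so local recruitment does not track local adults — and years-to-depletion
figures are therefore "without replenishment".

Rounding follows the field-report convention: half-up, densities to two
decimals before scaling by area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .domain import (
    ConsumptionRates,
    Island,
    IslandProfile,
    SizeRecord,
    SnailTransectPlot,
    Taxon,
    ValidationError,
)

__all__ = [
    "DepletionEstimate",
    "LifeHistoryProfile",
    "VulnerabilityAssessment",
    "round_half_up",
    "foraging_area",
    "shoreline_per_user",
    "transect_density",
    "standing_population",
    "annual_consumption",
    "depletion_assessment",
    "undersize_fraction",
    "assess_vulnerability",
    "tool_user_percentage",
    "population_density_per_km2",
    "ROCK_OYSTER_PROFILE",
    "PERIWINKLE_PROFILE",
]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero toward +inf (163.25 -> 163.3)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def foraging_area(profile: IslandProfile) -> float:
    """Foraging area in m^2: accessible shoreline x strip width, exact."""
    return profile.accessible_shoreline_m * profile.strip_width_m


def shoreline_per_user(profile: IslandProfile, decimals: int = 1) -> float:
    """Accessible shoreline (m) per tool user, rounded half-up."""
    return round_half_up(
        profile.accessible_shoreline_m / profile.n_tool_users, decimals
    )


def transect_density(
    transects: Sequence[SnailTransectPlot],
    species: Taxon,
    island: Island | None = None,
    decimals: int = 2,
) -> float:
    """Mean per-square-metre count of one species over the island's plots."""
    plots = [
        p for p in transects if island is None or p.island is island
    ]
    if not plots:
        raise ValidationError("density needs at least one transect plot")
    total = sum(p.count(species) for p in plots)
    area = sum(p.plot_side_m**2 for p in plots)
    return round_half_up(total / area, decimals)


def standing_population(
    transects: Sequence[SnailTransectPlot],
    species: Taxon,
    area_m2: float,
    island: Island | None = None,
    density_decimals: int = 2,
) -> int:
    """Standing stock: rounded transect density scaled to the foraging area."""
    if area_m2 <= 0:
        raise ValidationError("area_m2 must be > 0")
    density = transect_density(transects, species, island, density_decimals)
    return int(round_half_up(density * area_m2, 0))


def annual_consumption(
    rates: ConsumptionRates,
    n_users: int,
    basis: str = "daily_total",
    report_rounding: str = "none",
) -> float:
    """Yearly prey items consumed by the island's tool users.

    ``daily_total``       all shellfish: total items/day x users x days;
    ``hourly_periwinkle`` periwinkles only: items/hour x foraging hours/day
                          x users x days.
    ``report_rounding='nearest_thousand'`` rounds for report parity.
    """
    if n_users < 0:
        raise ValidationError("n_users must be >= 0")
    if basis == "daily_total":
        annual = rates.total_items_per_day * n_users * rates.days_per_year
    elif basis == "hourly_periwinkle":
        annual = (
            rates.periwinkles_per_hour
            * rates.foraging_hours_per_day
            * n_users
            * rates.days_per_year
        )
    else:
        raise ValueError(f"unknown consumption basis {basis!r}")
    if report_rounding == "nearest_thousand":
        return round_half_up(annual / 1000.0, 0) * 1000.0
    if report_rounding != "none":
        raise ValueError(f"unknown report_rounding {report_rounding!r}")
    return float(annual)


@dataclass(frozen=True)
class DepletionEstimate:
    """One island x species line of the depletion table."""

    island: Island
    species: Taxon
    foraging_area_m2: float
    density_per_m2: float
    standing_population: int
    annual_consumption: float
    depletion_ratio: float
    years_to_depletion: float  # without replenishment

    @property
    def depleted_within_year(self) -> bool:
        return self.depletion_ratio > 1.0


def depletion_assessment(
    standing: int,
    annual: float,
    island: Island = Island.KORAM,
    species: Taxon = Taxon.P_SULCATUS,
    area_m2: float = float("nan"),
    density: float = float("nan"),
) -> DepletionEstimate:
    """Depletion ratio (annual / standing) and years-to-depletion (1/ratio).

    Degenerate stocks are encoded as infinities rather than errors: an empty
    stock facing any consumption depletes immediately (ratio inf, years 0);
    zero consumption never depletes (ratio 0, years inf).
    """
    if standing < 0 or annual < 0:
        raise ValidationError("standing and annual must be >= 0")
    if standing == 0:
        ratio = math.inf if annual > 0 else 0.0
    else:
        ratio = annual / standing
    years = math.inf if ratio == 0 else 1.0 / ratio
    return DepletionEstimate(
        island=island,
        species=species,
        foraging_area_m2=area_m2,
        density_per_m2=density,
        standing_population=int(standing),
        annual_consumption=float(annual),
        depletion_ratio=float(ratio),
        years_to_depletion=float(years),
    )


def island_depletion(
    profile: IslandProfile,
    rates: ConsumptionRates,
    transects: Sequence[SnailTransectPlot],
    species: Taxon = Taxon.P_SULCATUS,
    basis: str = "hourly_periwinkle",
    density_decimals: int = 2,
) -> DepletionEstimate:
    """Full per-island pipeline: area -> density -> stock -> ratio."""
    area = foraging_area(profile)
    density = transect_density(transects, species, profile.island, density_decimals)
    standing = int(round_half_up(density * area, 0))
    annual = annual_consumption(rates, profile.n_tool_users, basis)
    return depletion_assessment(
        standing, annual, profile.island, species, area, density
    )


def undersize_fraction(
    sizes: Sequence[SizeRecord],
    reproductive_size_mm: float,
    island: Island | None = None,
    taxon: Taxon | None = None,
) -> tuple[float, int]:
    """Fraction of measured individuals strictly below reproductive size.

    The reproductive size threshold comes from the species literature and
    must be supplied by the caller; there is no default.
    """
    if reproductive_size_mm < 0:
        raise ValidationError("reproductive_size_mm must be >= 0")
    selected = [
        r
        for r in sizes
        if (island is None or r.island is island)
        and (taxon is None or r.taxon is taxon)
    ]
    if not selected:
        raise ValidationError("no size records selected")
    n = len(selected)
    below = sum(1 for r in selected if r.length_mm < reproductive_size_mm)
    return below / n, n


# ---------------------------------------------------------------------------
# life-history vulnerability rules

#: factor -> {level: predicted recovery}
VULNERABILITY_RULES: dict[str, dict[str, str]] = {
    "aggregation": {"high": "slow_recovery", "low": "fast_recovery"},
    "size_at_maturity": {"large": "slow_recovery", "small": "fast_recovery"},
    "reproductive_output": {"high": "fast_recovery", "low": "slow_recovery"},
    "larval_mode": {"attached": "slow_recovery", "planktonic": "fast_recovery"},
}


@dataclass(frozen=True)
class LifeHistoryProfile:
    """Qualitative life-history traits driving recovery from harvesting."""

    species: Taxon
    aggregation: str  # high | low
    size_at_maturity: str  # large | small
    reproductive_output: str  # high | low
    larval_mode: str  # attached | planktonic

    def __post_init__(self) -> None:
        for factor in VULNERABILITY_RULES:
            level = getattr(self, factor)
            if level not in VULNERABILITY_RULES[factor]:
                raise ValidationError(
                    f"{factor} must be one of "
                    f"{sorted(VULNERABILITY_RULES[factor])}, got {level!r}"
                )


@dataclass(frozen=True)
class VulnerabilityAssessment:
    species: Taxon
    predictions: Mapping[str, str]  # factor -> slow_recovery | fast_recovery
    summary: str  # vulnerable | resilient | mixed


def assess_vulnerability(profile: LifeHistoryProfile) -> VulnerabilityAssessment:
    """Apply the four recovery rules; summarise as vulnerable/resilient/mixed.

    ``vulnerable`` only when every factor predicts slow recovery,
    ``resilient`` only when every factor predicts fast recovery.
    """
    predictions = {
        factor: VULNERABILITY_RULES[factor][getattr(profile, factor)]
        for factor in VULNERABILITY_RULES
    }
    values = set(predictions.values())
    if values == {"slow_recovery"}:
        summary = "vulnerable"
    elif values == {"fast_recovery"}:
        summary = "resilient"
    else:
        summary = "mixed"
    return VulnerabilityAssessment(profile.species, predictions, summary)


#: rock oyster: dense beds, reproduces large in its first year, tens to
#: hundreds of millions of eggs, planktonic larvae
ROCK_OYSTER_PROFILE = LifeHistoryProfile(
    Taxon.OYSTER, "high", "large", "high", "planktonic"
)
#: tropical periwinkle: dense clusters, matures small in its second year,
#: low output with ~2% survival to maturity, planktonic larvae
PERIWINKLE_PROFILE = LifeHistoryProfile(
    Taxon.P_SULCATUS, "high", "small", "low", "planktonic"
)


# ---------------------------------------------------------------------------
# group-composition arithmetic


def tool_user_percentage(n_tool_users: int, n_candidates: int, decimals: int = 1) -> float:
    """Percent of candidate individuals that use tools (e.g. 25/36 -> 69.4)."""
    if n_candidates < 1:
        raise ValidationError("n_candidates must be >= 1")
    return round_half_up(100.0 * n_tool_users / n_candidates, decimals)


def population_density_per_km2(group_size: int, area_km2: float, decimals: int = 0) -> float:
    """Monkeys per square kilometre of island."""
    if area_km2 <= 0:
        raise ValidationError("area_km2 must be > 0")
    return round_half_up(group_size / area_km2, decimals)
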