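"""Typed data model, CSV I/O and record-level filters for the island surveys.

The surveys come from two neighbouring islands inhabited by stone-tool-using
macaque groups of very different size.  Five kinds of table are handled:

* stone tools collected after observed use (island, prey task, weight,
  dimensions, user identity),
* 20 x 20 cm quadrat surveys of naturally available stones,
* 1 x 1 m point-transect counts of three marine snail species,
* prey size measurements (oysters and snails),
* snail maturation-stage samples (ordinal gonad development vs. shell size),

plus two small parameter tables: per-island foraging profiles (shoreline,
tool-user counts) and per-individual shellfish consumption rates.

All linear dimensions are stored in millimetres and masses in grams; plot
sides keep their field units (cm for stone quadrats, m for snail plots).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Island",
    "Task",
    "Zone",
    "Taxon",
    "SNAIL_SPECIES",
    "ToolUseRecord",
    "StoneMeasurement",
    "StoneQuadrat",
    "SnailTransectPlot",
    "SizeRecord",
    "MaturationSample",
    "IslandProfile",
    "ConsumptionRates",
    "SurveyDataset",
    "SchemaError",
    "ValidationError",
    "read_survey_tables",
    "write_survey_tables",
    "filter_candidate_stones",
    "compute_prey_size",
]


class SchemaError(ValueError):
    """A CSV file does not match its documented schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class Island(str, Enum):
    """The two study islands; grouping factor of every comparison."""

    KORAM = "Koram"
    NOMSAO = "NomSao"

    @classmethod
    def parse(cls, label: str) -> "Island":
        for member in cls:
            if str(label).strip().lower() == member.value.lower():
                return member
        raise ValidationError(
            f"unknown island label {label!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class Task(str, Enum):
    OYSTER = "oyster"
    SNAIL = "snail"


class Zone(str, Enum):
    """Littoral zone of a stone quadrat."""

    OYSTER_BED = "oyster_bed"
    TIDAL = "tidal"


class Taxon(str, Enum):
    OYSTER = "oyster"
    P_SULCATUS = "P_sulcatus"
    C_BIFASCIATUS = "C_bifasciatus"
    M_LABIO = "M_labio"


#: the three snail species counted on the point transects
SNAIL_SPECIES: tuple[Taxon, ...] = (
    Taxon.P_SULCATUS,
    Taxon.C_BIFASCIATUS,
    Taxon.M_LABIO,
)


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be a positive finite number, got {value}")
    return value


@dataclass(frozen=True)
class ToolUseRecord:
    """One stone tool collected after (or at the site of) observed use."""

    island: Island
    tool_id: str
    task: Task
    weight_g: float
    length_mm: float | None = None
    width_mm: float | None = None
    depth_mm: float | None = None
    user_id: str | None = None
    user_class: str = "adult_male"
    provenance: str = "observed_use"

    def __post_init__(self) -> None:
        _positive("weight_g", self.weight_g)
        for dim in ("length_mm", "width_mm", "depth_mm"):
            v = getattr(self, dim)
            if v is not None:
                _positive(dim, v)


@dataclass(frozen=True)
class StoneMeasurement:
    """A single naturally occurring stone found in a quadrat."""

    weight_g: float
    length_mm: float | None = None
    width_mm: float | None = None

    def __post_init__(self) -> None:
        _positive("weight_g", self.weight_g)

    @property
    def max_dimension_mm(self) -> float | None:
        dims = [d for d in (self.length_mm, self.width_mm) if d is not None]
        return max(dims) if dims else None


@dataclass(frozen=True)
class StoneQuadrat:
    """One 20 x 20 cm stone-survey plot (lower littoral or oyster bed)."""

    island: Island
    location_index: int
    zone: Zone
    stones: tuple[StoneMeasurement, ...] = ()
    plot_side_cm: float = 20.0

    def __post_init__(self) -> None:
        if not 1 <= int(self.location_index):
            raise ValidationError("location_index must be >= 1")
        side_mm = self.plot_side_cm * 10.0
        for s in self.stones:
            if s.max_dimension_mm is not None and s.max_dimension_mm > side_mm:
                raise ValidationError(
                    f"stone dimension {s.max_dimension_mm} mm exceeds plot side "
                    f"{side_mm} mm"
                )

    @property
    def count(self) -> int:
        return len(self.stones)


@dataclass(frozen=True)
class SnailTransectPlot:
    """One 1 x 1 m snail point-transect plot with per-species counts."""

    island: Island
    transect_index: int
    counts: Mapping[Taxon, int]
    plot_side_m: float = 1.0

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if int(c) < 0:
                raise ValidationError(f"negative count {c} for {sp}")

    def count(self, species: Taxon) -> int:
        return int(self.counts.get(species, 0))


@dataclass(frozen=True)
class SizeRecord:
    """One measured prey individual (cracked oyster or collected snail)."""

    island: Island
    taxon: Taxon
    length_mm: float
    width_mm: float | None = None
    weight_g: float | None = None

    def __post_init__(self) -> None:
        _positive("length_mm", self.length_mm)
        if self.width_mm is not None:
            _positive("width_mm", self.width_mm)
        if self.weight_g is not None and self.weight_g < 0:
            raise ValidationError("weight_g must be >= 0")

    @property
    def derived_size(self) -> float:
        """Default size proxy: area for oysters, conical volume for snails."""
        method = "oyster_area" if self.taxon is Taxon.OYSTER else "snail_volume"
        return compute_prey_size(self, method)


MATURATION_STAGES = {
    1: "immature",
    2: "subadult",
    3: "mature",
    4: "completely_mature",
}


@dataclass(frozen=True)
class MaturationSample:
    """A snail sampled for gonad staging, with its field size category."""

    island: Island
    species: Taxon
    size_category: int
    shell_size_mm: float
    stage: int

    def __post_init__(self) -> None:
        if self.size_category not in (1, 2, 3, 4):
            raise ValidationError("size_category must be in 1..4")
        if self.stage not in MATURATION_STAGES:
            raise ValidationError("stage must be in 1..4")
        _positive("shell_size_mm", self.shell_size_mm)
        if self.species is Taxon.OYSTER:
            raise ValidationError("maturation staging applies to snails only")


@dataclass(frozen=True)
class IslandProfile:
    """Per-island foraging geometry and tool-user head count."""

    island: Island
    n_tool_users: int
    accessible_shoreline_m: float
    strip_width_m: float = 3.0
    group_size: int | None = None
    area_km2: float | None = None

    def __post_init__(self) -> None:
        if self.accessible_shoreline_m < 0:
            raise ValidationError("accessible_shoreline_m must be >= 0")
        if self.strip_width_m <= 0:
            raise ValidationError("strip_width_m must be > 0")
        if self.n_tool_users < 1:
            raise ValidationError("n_tool_users must be >= 1")


@dataclass(frozen=True)
class ConsumptionRates:
    """Per-individual shellfish consumption rates from focal observations.

    ``oysters_per_day`` and ``other_per_day`` are whole-day totals;
    ``periwinkles_per_hour`` is per foraging hour (low tide).

    .. warning::
       The field report's own headline total treats the periwinkle figure as
       a daily count, so ``total_items_per_day`` defaults to the plain sum of
       the three components (36 + 1.6 + 8.9 = 46.5), while periwinkle-only
       extrapolations multiply the hourly rate by the foraging hours
       (1.6/h x 4 h = 6.4/day).  These two readings are mutually
       inconsistent but both are kept, because each is what the per-basis
       totals are built from.  Pass ``total_items_per_day`` explicitly to
       override.
    """

    oysters_per_day: float
    periwinkles_per_hour: float
    other_per_day: float
    foraging_hours_per_day: float = 4.0
    days_per_year: int = 365
    total_items_per_day: float | None = None

    def __post_init__(self) -> None:
        for name in ("oysters_per_day", "periwinkles_per_hour", "other_per_day"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.total_items_per_day is None:
            daily = (
                self.oysters_per_day
                + self.periwinkles_per_hour
                + self.other_per_day
            )
            logger.info(
                "total_items_per_day defaulted to the plain component sum "
                "%.1f/day (periwinkles entered as a daily figure); the "
                "periwinkle-only basis instead uses %.1f/h x %.0f h",
                daily, self.periwinkles_per_hour, self.foraging_hours_per_day,
            )
            object.__setattr__(self, "total_items_per_day", daily)


# ---------------------------------------------------------------------------
# record-level filters and derived quantities


def filter_candidate_stones(
    stones: Sequence[StoneMeasurement],
    min_tool_weight_g: float,
    plot_side_mm: float = 200.0,
) -> list[StoneMeasurement]:
    """Keep quadrat stones that are plausible tool candidates.

    A stone is retained when its weight is at least 80% of the lightest tool
    the monkeys were observed to use (stones more than 20% smaller than the
    smallest tool are excluded) and no measured dimension exceeds the plot
    side.  The threshold is inclusive and input order is preserved.
    """
    min_tool_weight_g = _positive("min_tool_weight_g", min_tool_weight_g)
    threshold = 0.8 * min_tool_weight_g
    kept = []
    for s in stones:
        if s.weight_g < 0:
            raise ValidationError("stone weight must be >= 0")
        if s.weight_g < threshold:
            continue
        if s.max_dimension_mm is not None and s.max_dimension_mm > plot_side_mm:
            continue
        kept.append(s)
    return kept


def compute_prey_size(record: SizeRecord, method: str = "oyster_area") -> float:
    """Size proxy for one prey individual.

    ``oyster_area``   length x width (mm^2), the footprint of the opened valve;
    ``snail_volume``  cone volume (1/3) pi (width/2)^2 length (mm^3), treating
                      the spiral shell as a cone;
    ``length_only``   maximum shell length (mm).
    """
    if method == "length_only":
        return float(record.length_mm)
    if record.width_mm is None:
        raise ValidationError(f"method {method!r} requires width_mm")
    if method == "oyster_area":
        return float(record.length_mm * record.width_mm)
    if method == "snail_volume":
        return float(
            math.pi / 3.0 * (record.width_mm / 2.0) ** 2 * record.length_mm
        )
    raise ValueError(f"unknown size method {method!r}")


def default_size_method(taxon: Taxon) -> str:
    return "oyster_area" if taxon is Taxon.OYSTER else "snail_volume"


# ---------------------------------------------------------------------------
# dataset bundle


@dataclass
class SurveyDataset:
    """All survey collections for the two islands, ready for analysis."""

    tools: list[ToolUseRecord] = field(default_factory=list)
    stone_quadrats: list[StoneQuadrat] = field(default_factory=list)
    snail_transects: list[SnailTransectPlot] = field(default_factory=list)
    prey_sizes: list[SizeRecord] = field(default_factory=list)
    maturation: list[MaturationSample] = field(default_factory=list)
    profiles: dict[Island, IslandProfile] = field(default_factory=dict)
    consumption: ConsumptionRates | None = None

    # -- convenient views -------------------------------------------------

    def tools_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "island": [t.island.value for t in self.tools],
                "tool_id": [t.tool_id for t in self.tools],
                "task": [t.task.value for t in self.tools],
                "weight_g": [t.weight_g for t in self.tools],
                "user_id": [t.user_id for t in self.tools],
                "user_class": [t.user_class for t in self.tools],
            }
        )

    def analysis_tools(self, task: Task) -> list[ToolUseRecord]:
        """Tools entering the island comparison for one prey task.

        Only adult-male tools are comparable across islands (the smaller
        island hosts adult males exclusively), so other user classes are
        dropped here.
        """
        return [
            t
            for t in self.tools
            if t.task is task and t.user_class in ("adult_male", "unknown")
        ]

    def tool_counts(self) -> dict[tuple[Island, Task], int]:
        out: dict[tuple[Island, Task], int] = {}
        for t in self.tools:
            key = (t.island, t.task)
            out[key] = out.get(key, 0) + 1
        return out

    def transect_counts(self, island: Island) -> dict[Taxon, int]:
        """Total per-species snail counts over all transects of one island."""
        totals = {sp: 0 for sp in SNAIL_SPECIES}
        for plot in self.snail_transects:
            if plot.island is island:
                for sp in SNAIL_SPECIES:
                    totals[sp] += plot.count(sp)
        return totals


# ---------------------------------------------------------------------------
# CSV schemas and I/O

TOOL_COLUMNS = [
    "island",
    "tool_id",
    "task",
    "weight_g",
    "length_mm",
    "width_mm",
    "depth_mm",
    "user_id",
    "user_class",
    "provenance",
]
STONE_COLUMNS = [
    "island",
    "location_index",
    "zone",
    "stone_weight_g",
    "stone_length_mm",
    "stone_width_mm",
]
SNAIL_COLUMNS = ["island", "transect_index", "species", "count"]
SIZE_COLUMNS = ["island", "taxon", "length_mm", "width_mm", "weight_g"]
MATURATION_COLUMNS = ["island", "species", "size_category", "shell_size_mm", "stage"]
PROFILE_COLUMNS = [
    "island",
    "n_tool_users",
    "accessible_shoreline_m",
    "strip_width_m",
    "group_size",
    "area_km2",
]
RATE_COLUMNS = [
    "oysters_per_day",
    "periwinkles_per_hour",
    "other_per_day",
    "foraging_hours_per_day",
    "days_per_year",
]

_REQUIRED = {
    "tools": ["island", "tool_id", "task", "weight_g"],
    "stone_quadrats": ["island", "location_index", "zone", "stone_weight_g"],
    "snail_transects": SNAIL_COLUMNS,
    "prey_sizes": ["island", "taxon", "length_mm"],
    "maturation": MATURATION_COLUMNS,
    "island_profiles": ["island", "n_tool_users", "accessible_shoreline_m"],
    "consumption_rates": ["oysters_per_day", "periwinkles_per_hour", "other_per_day"],
}


def _load_csv(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {kind} table is missing column(s) {missing}")
    known = set(_REQUIRED[kind]) | set(
        {
            "tools": TOOL_COLUMNS,
            "stone_quadrats": STONE_COLUMNS,
            "snail_transects": SNAIL_COLUMNS,
            "prey_sizes": SIZE_COLUMNS,
            "maturation": MATURATION_COLUMNS,
            "island_profiles": PROFILE_COLUMNS,
            "consumption_rates": RATE_COLUMNS,
        }[kind]
    )
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        df = df.drop(columns=extra)
    return df


def _num(row: pd.Series, col: str, kind: str, idx: int, optional: bool = False):
    raw = row.get(col)
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or (
        isinstance(raw, str) and raw.strip() == ""
    ):
        if optional:
            return None
        raise SchemaError(f"{kind} row {idx}: missing value in column {col!r}")
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{kind} row {idx}: non-numeric value {raw!r} in column {col!r}"
        ) from None


def _opt_str(row: pd.Series, col: str) -> str | None:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    v = str(v).strip()
    return v or None


def read_survey_tables(paths: Mapping[str, str | Path]) -> SurveyDataset:
    """Load and validate any subset of the survey CSV tables.

    ``paths`` maps table kinds (``tools``, ``stone_quadrats``,
    ``snail_transects``, ``prey_sizes``, ``maturation``, ``island_profiles``,
    ``consumption_rates``) to file paths; absent kinds yield empty
    collections.
    """
    ds = SurveyDataset()
    unknown = set(paths) - set(_REQUIRED)
    if unknown:
        raise SchemaError(f"unknown table kind(s): {sorted(unknown)}")

    if "tools" in paths:
        df = _load_csv(paths["tools"], "tools")
        for idx, row in df.iterrows():
            ds.tools.append(
                ToolUseRecord(
                    island=Island.parse(row["island"]),
                    tool_id=str(row["tool_id"]),
                    task=Task(str(row["task"]).strip()),
                    weight_g=_num(row, "weight_g", "tools", idx),
                    length_mm=_num(row, "length_mm", "tools", idx, optional=True),
                    width_mm=_num(row, "width_mm", "tools", idx, optional=True),
                    depth_mm=_num(row, "depth_mm", "tools", idx, optional=True),
                    user_id=_opt_str(row, "user_id"),
                    user_class=_opt_str(row, "user_class") or "adult_male",
                    provenance=_opt_str(row, "provenance") or "observed_use",
                )
            )

    if "stone_quadrats" in paths:
        df = _load_csv(paths["stone_quadrats"], "stone_quadrats")
        groups: dict[tuple[Island, int, Zone], list[StoneMeasurement]] = {}
        for idx, row in df.iterrows():
            key = (
                Island.parse(row["island"]),
                int(_num(row, "location_index", "stone_quadrats", idx)),
                Zone(str(row["zone"]).strip()),
            )
            groups.setdefault(key, [])
            w = _num(row, "stone_weight_g", "stone_quadrats", idx, optional=True)
            if w is not None:  # a row with empty weight marks an empty plot
                groups[key].append(
                    StoneMeasurement(
                        weight_g=w,
                        length_mm=_num(
                            row, "stone_length_mm", "stone_quadrats", idx, optional=True
                        ),
                        width_mm=_num(
                            row, "stone_width_mm", "stone_quadrats", idx, optional=True
                        ),
                    )
                )
        for (island, loc, zone), stones in groups.items():
            ds.stone_quadrats.append(
                StoneQuadrat(island, loc, zone, tuple(stones))
            )

    if "snail_transects" in paths:
        df = _load_csv(paths["snail_transects"], "snail_transects")
        counts: dict[tuple[Island, int], dict[Taxon, int]] = {}
        for idx, row in df.iterrows():
            key = (
                Island.parse(row["island"]),
                int(_num(row, "transect_index", "snail_transects", idx)),
            )
            sp = Taxon(str(row["species"]).strip())
            counts.setdefault(key, {})[sp] = int(
                _num(row, "count", "snail_transects", idx)
            )
        for (island, tix), cmap in counts.items():
            ds.snail_transects.append(SnailTransectPlot(island, tix, cmap))

    if "prey_sizes" in paths:
        df = _load_csv(paths["prey_sizes"], "prey_sizes")
        for idx, row in df.iterrows():
            ds.prey_sizes.append(
                SizeRecord(
                    island=Island.parse(row["island"]),
                    taxon=Taxon(str(row["taxon"]).strip()),
                    length_mm=_num(row, "length_mm", "prey_sizes", idx),
                    width_mm=_num(row, "width_mm", "prey_sizes", idx, optional=True),
                    weight_g=_num(row, "weight_g", "prey_sizes", idx, optional=True),
                )
            )

    if "maturation" in paths:
        df = _load_csv(paths["maturation"], "maturation")
        for idx, row in df.iterrows():
            ds.maturation.append(
                MaturationSample(
                    island=Island.parse(row["island"]),
                    species=Taxon(str(row["species"]).strip()),
                    size_category=int(_num(row, "size_category", "maturation", idx)),
                    shell_size_mm=_num(row, "shell_size_mm", "maturation", idx),
                    stage=int(_num(row, "stage", "maturation", idx)),
                )
            )

    if "island_profiles" in paths:
        df = _load_csv(paths["island_profiles"], "island_profiles")
        for idx, row in df.iterrows():
            island = Island.parse(row["island"])
            strip = _num(row, "strip_width_m", "island_profiles", idx, optional=True)
            group = _num(row, "group_size", "island_profiles", idx, optional=True)
            area = _num(row, "area_km2", "island_profiles", idx, optional=True)
            ds.profiles[island] = IslandProfile(
                island=island,
                n_tool_users=int(_num(row, "n_tool_users", "island_profiles", idx)),
                accessible_shoreline_m=_num(
                    row, "accessible_shoreline_m", "island_profiles", idx
                ),
                strip_width_m=strip if strip is not None else 3.0,
                group_size=int(group) if group is not None else None,
                area_km2=area,
            )

    if "consumption_rates" in paths:
        df = _load_csv(paths["consumption_rates"], "consumption_rates")
        if len(df) > 0:
            row = df.iloc[0]
            hours = _num(row, "foraging_hours_per_day", "consumption_rates", 0, True)
            days = _num(row, "days_per_year", "consumption_rates", 0, True)
            ds.consumption = ConsumptionRates(
                oysters_per_day=_num(row, "oysters_per_day", "consumption_rates", 0),
                periwinkles_per_hour=_num(
                    row, "periwinkles_per_hour", "consumption_rates", 0
                ),
                other_per_day=_num(row, "other_per_day", "consumption_rates", 0),
                foraging_hours_per_day=hours if hours is not None else 4.0,
                days_per_year=int(days) if days is not None else 365,
            )
    return ds


def write_survey_tables(dataset: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every non-empty collection as a CSV; returns the path map.

    The written files round-trip through :func:`read_survey_tables`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    def _write(kind: str, filename: str, columns: list[str], rows: list[list]) -> None:
        path = out_dir / filename
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(",".join(columns) + "\n")
            for r in rows:
                fh.write(",".join(_fmt(v) for v in r) + "\n")
        paths[kind] = path

    if dataset.tools:
        _write(
            "tools",
            "tools.csv",
            TOOL_COLUMNS,
            [
                [
                    t.island.value,
                    t.tool_id,
                    t.task.value,
                    t.weight_g,
                    t.length_mm,
                    t.width_mm,
                    t.depth_mm,
                    t.user_id,
                    t.user_class,
                    t.provenance,
                ]
                for t in dataset.tools
            ],
        )
    if dataset.stone_quadrats:
        rows = []
        for q in dataset.stone_quadrats:
            if not q.stones:
                rows.append([q.island.value, q.location_index, q.zone.value, None, None, None])
            for s in q.stones:
                rows.append(
                    [
                        q.island.value,
                        q.location_index,
                        q.zone.value,
                        s.weight_g,
                        s.length_mm,
                        s.width_mm,
                    ]
                )
        _write("stone_quadrats", "stone_quadrats.csv", STONE_COLUMNS, rows)
    if dataset.snail_transects:
        rows = [
            [p.island.value, p.transect_index, sp.value, p.count(sp)]
            for p in dataset.snail_transects
            for sp in SNAIL_SPECIES
        ]
        _write("snail_transects", "snail_transects.csv", SNAIL_COLUMNS, rows)
    if dataset.prey_sizes:
        _write(
            "prey_sizes",
            "prey_sizes.csv",
            SIZE_COLUMNS,
            [
                [r.island.value, r.taxon.value, r.length_mm, r.width_mm, r.weight_g]
                for r in dataset.prey_sizes
            ],
        )
    if dataset.maturation:
        _write(
            "maturation",
            "maturation.csv",
            MATURATION_COLUMNS,
            [
                [
                    m.island.value,
                    m.species.value,
                    m.size_category,
                    m.shell_size_mm,
                    m.stage,
                ]
                for m in dataset.maturation
            ],
        )
    if dataset.profiles:
        _write(
            "island_profiles",
            "island_profiles.csv",
            PROFILE_COLUMNS,
            [
                [
                    p.island.value,
                    p.n_tool_users,
                    p.accessible_shoreline_m,
                    p.strip_width_m,
                    p.group_size,
                    p.area_km2,
                ]
                for p in dataset.profiles.values()
            ],
        )
    if dataset.consumption is not None:
        c = dataset.consumption
        _write(
            "consumption_rates",
            "consumption_rates.csv",
            RATE_COLUMNS,
            [
                [
                    c.oysters_per_day,
                    c.periwinkles_per_hour,
                    c.other_per_day,
                    c.foraging_hours_per_day,
                    c.days_per_year,
                ]
            ],
        )
    return paths
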