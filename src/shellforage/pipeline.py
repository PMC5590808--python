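"""End-to-end orchestration: simulate or load surveys, run every applicable
comparison stage, and write result tables plus a reproducibility manifest.

Stages (each skipped with a logged reason when its inputs are absent):

1. tool-weights   — oyster-tool mixed model and snail-tool linear model,
                    each with its permutation companion and (for the mixed
                    model) leave-one-out stability;
2. stone-supply   — candidate-stone filter, count and weight comparisons;
3. availability   — per-species transect-count comparisons;
4. prey-size      — per-taxon size comparisons with bootstrap CIs;
5. maturation     — size-category model (full-vs-null and island term);
6. depletion      — foraging areas, standing stocks, annual consumption,
                    depletion ratios, and life-history vulnerability.

Reruns with the same config are bit-identical: every stage draws its seed
deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .domain import (
    Island,
    StoneQuadrat,
    SurveyDataset,
    Task,
    Taxon,
    filter_candidate_stones,
    read_survey_tables,
    write_survey_tables,
)
from .depletion import (
    PERIWINKLE_PROFILE,
    ROCK_OYSTER_PROFILE,
    assess_vulnerability,
    island_depletion,
    shoreline_per_user,
    undersize_fraction,
)
from .models import (
    MaturationModel,
    OysterToolModel,
    SnailToolModel,
    compare_availability,
    compare_prey_sizes,
    compare_stone_supply,
    tools_to_frame,
)
from .simulate import SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """What to run and how: exactly one of ``paths``/``simulation`` is set."""

    paths: Mapping[str, str] | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0
    n_perm: int = 10000
    n_boot: int = 1000
    ci_level: float = 0.95
    density_decimals: int = 2
    run_permutations: bool = True
    run_stability: bool = True
    periwinkle_reproductive_size_mm: float | None = None
    out_dir: str | Path = "shellforage_results"

    def __post_init__(self) -> None:
        if (self.paths is None) == (self.simulation is None):
            raise ValueError(
                "configure exactly one of input paths or a simulation"
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML (or JSON, a YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        if "size_profile" in sim:
            sim["size_profile"] = {
                Taxon(k): tuple(v) for k, v in sim["size_profile"].items()
            }
        sim = SimulationConfig(**sim)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(simulation=sim, **raw)


@dataclass
class ReportBundle:
    """Stage result tables (lists of row dicts) plus the run manifest."""

    tables: dict[str, list[dict[str, Any]]] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, ss.spawn(len(names)))
    }


_STAGES = [
    "tool_weights",
    "stone_supply",
    "availability",
    "prey_size",
    "maturation",
    "depletion",
]


def _fitresult_row(model: str, term: str, fr, seed=None) -> dict[str, Any]:
    df1, df2 = fr.df
    return {
        "model": model,
        "term": term,
        "estimate": fr.estimate,
        "se": fr.se,
        "statistic": fr.statistic,
        "df1": df1,
        "df2": df2,
        "p": fr.p_value,
        "transform": fr.transform,
        "n": fr.n,
        "seed": seed,
    }


def _stage_tool_weights(ds: SurveyDataset, cfg: PipelineConfig, seed: int):
    rows = []
    oyster = ds.analysis_tools(Task.OYSTER)
    snail = ds.analysis_tools(Task.SNAIL)
    if oyster:
        res = OysterToolModel(tools_to_frame(oyster)).fit()
        rows.append(_fitresult_row("oyster_tool_lmm", "island", res.fit_result))
        if cfg.run_permutations:
            perm = res.permutation_test(n_perm=cfg.n_perm, seed=seed)
            rows.append(
                {
                    "model": "oyster_tool_lmm",
                    "term": "island_permutation",
                    "statistic": perm.observed_stat,
                    "p": perm.p_value,
                    "n": res.n,
                    "seed": seed,
                }
            )
        if cfg.run_stability:
            stab = res.leave_one_out()
            rows.append(
                {
                    "model": "oyster_tool_lmm",
                    "term": "leave_one_out",
                    "estimate": res.estimate,
                    "statistic": stab.range[1] - stab.range[0],
                    "n": len(stab.per_unit),
                    "influential": ";".join(stab.influential),
                }
            )
    else:
        logger.info("no oyster tools; mixed model skipped")
    if snail:
        res = SnailToolModel(tools_to_frame(snail)).fit()
        rows.append(_fitresult_row("snail_tool_lm", "island", res.fit_result))
        if cfg.run_permutations:
            perm = res.permutation_test(n_perm=cfg.n_perm, seed=seed + 1)
            rows.append(
                {
                    "model": "snail_tool_lm",
                    "term": "island_permutation",
                    "statistic": perm.observed_stat,
                    "p": perm.p_value,
                    "n": res.n,
                    "seed": seed + 1,
                }
            )
    else:
        logger.info("no snail tools; linear model skipped")
    if not rows:
        raise _SkipStage("no tool records")
    return rows


def _stage_stone_supply(ds: SurveyDataset, cfg: PipelineConfig, seed: int):
    if not ds.stone_quadrats:
        raise _SkipStage("no stone quadrats")
    quadrats = ds.stone_quadrats
    oyster_tools = ds.analysis_tools(Task.OYSTER) + ds.analysis_tools(Task.SNAIL)
    koram_weights = [
        t.weight_g for t in oyster_tools if t.island is Island.KORAM
    ]
    if koram_weights:
        min_tool = min(koram_weights)
        filtered = []
        n_before = n_after = 0
        for q in quadrats:
            kept = filter_candidate_stones(list(q.stones), min_tool)
            n_before += len(q.stones)
            n_after += len(kept)
            filtered.append(
                StoneQuadrat(q.island, q.location_index, q.zone, tuple(kept))
            )
        logger.info(
            "candidate-stone filter (>= 0.8 x %.1f g): %d of %d stones kept",
            min_tool, n_after, n_before,
        )
        quadrats = filtered
    cmp = compare_stone_supply(
        quadrats, n_boot=cfg.n_boot, level=cfg.ci_level, seed=seed
    )
    rows = [
        {
            "model": "stone_supply",
            "term": "counts_t",
            "statistic": cmp.counts_test.statistic,
            "df1": cmp.counts_test.df,
            "p": cmp.counts_test.p_value,
        },
        {
            "model": "stone_supply",
            "term": "weights_t",
            "statistic": cmp.weights_test.statistic,
            "df1": cmp.weights_test.df,
            "p": cmp.weights_test.p_value,
        },
    ]
    for (isl, zone), ci in sorted(cmp.weight_ci.items()):
        rows.append(
            {
                "model": "stone_supply",
                "term": f"weight_ci:{isl}:{zone}",
                "estimate": ci.point,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "seed": ci.seed,
            }
        )
    for (isl, zone), ci in sorted(cmp.count_ci.items()):
        rows.append(
            {
                "model": "stone_supply",
                "term": f"count_ci:{isl}:{zone}",
                "estimate": ci.point,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "seed": ci.seed,
            }
        )
    return rows


def _stage_availability(ds: SurveyDataset, cfg: PipelineConfig, seed: int):
    if not ds.snail_transects:
        raise _SkipStage("no snail transects")
    rows = []
    for i, species in enumerate(
        (Taxon.P_SULCATUS, Taxon.C_BIFASCIATUS, Taxon.M_LABIO)
    ):
        try:
            cmp = compare_availability(
                ds.snail_transects, species,
                n_boot=cfg.n_boot, level=cfg.ci_level, seed=seed + i,
            )
        except ValueError as err:
            logger.info("availability for %s skipped: %s", species.value, err)
            continue
        row = {
            "model": "availability",
            "term": species.value,
            "statistic": cmp.test.statistic if cmp.test else None,
            "df1": cmp.test.df if cmp.test else None,
            "p": cmp.test.p_value if cmp.test else None,
            "seed": seed + i,
        }
        for isl, ci in cmp.ci.items():
            row[f"mean_{isl}"] = ci.point
            row[f"ci_lower_{isl}"] = ci.lower
            row[f"ci_upper_{isl}"] = ci.upper
        rows.append(row)
    return rows


def _stage_prey_size(ds: SurveyDataset, cfg: PipelineConfig, seed: int):
    if not ds.prey_sizes:
        raise _SkipStage("no prey size records")
    rows = []
    taxa = sorted({r.taxon for r in ds.prey_sizes}, key=lambda t: t.value)
    for i, taxon in enumerate(taxa):
        cmp = compare_prey_sizes(
            ds.prey_sizes, taxon,
            n_boot=cfg.n_boot, level=cfg.ci_level, seed=seed + i,
        )
        row = {
            "model": "prey_size",
            "term": taxon.value,
            "skipped": cmp.skipped,
            "skip_reason": cmp.skip_reason,
            "seed": seed + i,
        }
        if not cmp.skipped:
            row.update(
                statistic=cmp.test.statistic,
                df1=cmp.test.df,
                p=cmp.test.p_value,
                ci_overlap=cmp.overlap,
            )
            for isl, ci in cmp.ci.items():
                row[f"mean_{isl}"] = ci.point
                row[f"ci_lower_{isl}"] = ci.lower
                row[f"ci_upper_{isl}"] = ci.upper
        rows.append(row)
    return rows


def _stage_maturation(ds: SurveyDataset, cfg: PipelineConfig, seed: int):
    if not ds.maturation:
        raise _SkipStage("no maturation samples")
    res = MaturationModel.from_records(ds.maturation).fit()
    return [
        _fitresult_row("maturation_lm", "full_vs_null", res.full_vs_null),
        _fitresult_row("maturation_lm", "island", res.island_effect),
    ]


def _stage_depletion(ds: SurveyDataset, cfg: PipelineConfig, seed: int):
    if not ds.profiles or ds.consumption is None:
        raise _SkipStage("no island profiles / consumption rates")
    rows = []
    for island, profile in sorted(ds.profiles.items(), key=lambda kv: kv[0].value):
        row = {
            "model": "depletion",
            "term": f"{island.value}:all_shellfish",
            "annual": ds.consumption.total_items_per_day
            * profile.n_tool_users
            * ds.consumption.days_per_year,
            "shoreline_per_user_m": shoreline_per_user(profile),
        }
        rows.append(row)
        if ds.snail_transects:
            est = island_depletion(
                profile, ds.consumption, ds.snail_transects,
                species=Taxon.P_SULCATUS,
                density_decimals=cfg.density_decimals,
            )
            rows.append(
                {
                    "model": "depletion",
                    "term": f"{island.value}:{est.species.value}",
                    "area_m2": est.foraging_area_m2,
                    "density": est.density_per_m2,
                    "standing": est.standing_population,
                    "annual": est.annual_consumption,
                    "ratio": est.depletion_ratio,
                    "years_without_replenishment": est.years_to_depletion,
                }
            )
        if cfg.periwinkle_reproductive_size_mm and ds.prey_sizes:
            try:
                frac, n = undersize_fraction(
                    ds.prey_sizes, cfg.periwinkle_reproductive_size_mm,
                    island=island, taxon=Taxon.P_SULCATUS,
                )
                rows.append(
                    {
                        "model": "depletion",
                        "term": f"{island.value}:undersize_periwinkle",
                        "estimate": frac,
                        "n": n,
                    }
                )
            except ValueError:
                pass
    for profile_lh in (ROCK_OYSTER_PROFILE, PERIWINKLE_PROFILE):
        va = assess_vulnerability(profile_lh)
        row = {
            "model": "vulnerability",
            "term": va.species.value,
            "summary": va.summary,
        }
        row.update(va.predictions)
        rows.append(row)
    return rows


class _SkipStage(Exception):
    pass


_STAGE_FNS = {
    "tool_weights": _stage_tool_weights,
    "stone_supply": _stage_stone_supply,
    "availability": _stage_availability,
    "prey_size": _stage_prey_size,
    "maturation": _stage_maturation,
    "depletion": _stage_depletion,
}


def _write_table(rows: list[dict[str, Any]], path: Path) -> None:
    columns: list[str] = []
    for r in rows:
        for k in r:
            if k not in columns:
                columns.append(k)

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(columns) + "\n")
        for r in rows:
            fh.write(",".join(fmt(r.get(c)) for c in columns) + "\n")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every applicable stage; write CSV tables and a JSON manifest.

    Stage failures are recorded in the manifest and reflected in
    ``bundle.ok``; completed stages keep their outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()

    if config.simulation is not None:
        ds = generate_dataset(config.simulation)
        input_desc = {"simulation_seed": config.simulation.seed}
        write_survey_tables(ds, out_dir / "synthetic_input")
    else:
        ds = read_survey_tables(config.paths)
        input_desc = {"paths": {k: str(v) for k, v in config.paths.items()}}

    seeds = _stage_seeds(config.seed, _STAGES)
    counts = {
        "tools": len(ds.tools),
        "stone_quadrats": len(ds.stone_quadrats),
        "snail_transects": len(ds.snail_transects),
        "prey_sizes": len(ds.prey_sizes),
        "maturation": len(ds.maturation),
    }
    for stage in _STAGES:
        try:
            rows = _STAGE_FNS[stage](ds, config, seeds[stage])
        except _SkipStage as skip:
            logger.info("stage %s skipped: %s", stage, skip)
            bundle.manifest.setdefault("skipped", {})[stage] = str(skip)
            continue
        except Exception as err:
            logger.error("stage %s failed: %s", stage, err)
            bundle.errors[stage] = f"{type(err).__name__}: {err}"
            continue
        bundle.tables[stage] = rows
        _write_table(rows, out_dir / f"{stage}.csv")

    bundle.manifest.update(
        {
            "version": __version__,
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "ci_level": config.ci_level,
            "input": input_desc,
            "row_counts": counts,
            "stages_written": sorted(bundle.tables),
            "errors": bundle.errors,
        }
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
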