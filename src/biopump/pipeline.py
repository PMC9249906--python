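"""End-to-end convenience runner: rasters in, summary statistics out.

Chains the five identification filters, zonal consolidation, species
matching, turnover + erosion simulation and reporting. The CLI and the
synthetic-world round-trip tests both go through this path so the wiring
between modules is exercised exactly once, in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .geodata import RasterLayer, cell_area_ha
from .marginal_land import (LandCoverLegend, MarginalLandMask, identify_marginal_land,
                            load_severity_codes)
from .consolidate import TargetArea, assign_zones, consolidate_target_areas, summarize_areas
from .plants import SpeciesRecord, load_species
from .match_engine import MatchConfig, match_all, matches_to_frame
from .scenario import SimConfig, report, select_best_case, simulate_matched

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    marginal: MarginalLandMask
    zone_dropped: int
    areas: list[TargetArea]
    species: list[SpeciesRecord]
    matches: list
    simulations: list
    best_cases: pd.DataFrame
    summary: dict
    area_summary: dict


def run_pipeline(
    rasters: dict[str, RasterLayer],
    climate_rasters: dict[str, list[RasterLayer]],
    species_table,
    *,
    legend: LandCoverLegend | None = None,
    severity_codes=None,
    soc_threshold: float = 50.0,
    match_config: MatchConfig = MatchConfig(),
    sim_config: SimConfig = SimConfig(),
) -> PipelineResult:
    """Run identify → consolidate → match → simulate → report.

    ``rasters`` must provide lc_t0, lc_t1, soc, protected, problem,
    regions, gez, clay_pct, ph, texture, bulk_density, soil_depth_cm,
    elevation_m, slope_pct and soil_loss, all on one shared grid;
    ``climate_rasters`` provides 12 monthly layers each for temp, prec
    and pet.
    """
    legend = legend or LandCoverLegend.from_csv()
    severity_codes = severity_codes if severity_codes is not None else load_severity_codes()
    areas_grid = cell_area_ha(rasters["soc"])

    marginal = identify_marginal_land(
        rasters["lc_t0"], rasters["lc_t1"], rasters["soc"],
        rasters["protected"], rasters["problem"], legend, severity_codes,
        soc_threshold=soc_threshold, cell_areas=areas_grid,
    )
    zone_raster, dropped = assign_zones(marginal, rasters["regions"], rasters["gez"])
    areas = consolidate_target_areas(
        marginal, zone_raster, climate_rasters,
        soil={k: rasters[k] for k in ("clay_pct", "ph", "texture", "bulk_density", "soil_depth_cm")},
        terrain={k: rasters[k] for k in ("elevation_m", "slope_pct")},
        soil_loss=rasters["soil_loss"], soc=rasters["soc"],
    )
    species, rejected = load_species(species_table)
    matches = match_all(species, areas, match_config)
    sims = simulate_matched(matches, areas, species, sim_config)
    best = select_best_case(sims)
    summary = report(
        matches, sims, best,
        n_areas=len(areas), n_species=len(species),
        species_by_taxon={s.taxon: s for s in species},
        n_inventoried_species=len(species),
    )
    summary["rejected_species_rows"] = len(rejected)
    return PipelineResult(
        marginal=marginal, zone_dropped=dropped, areas=areas, species=species,
        matches=matches, simulations=sims, best_cases=best, summary=summary,
        area_summary=summarize_areas(areas),
    )
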