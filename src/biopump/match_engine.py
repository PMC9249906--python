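"""Pedoclimatic matching of species to target areas.

A species matches a target area when every tested tolerance holds: mean
annual temperature and annual precipitation sum inside the species'
absolute ranges, area pH and elevation inside range, the area's modal soil
texture among the tolerated textures, and the area's ecological zone among
the species' compatible zones. Matching is binary — no partial credit or
suitability scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consolidate import TargetArea
from .plants import SpeciesRecord

__all__ = ["MatchConfig", "MatchResult", "is_match", "match_all", "count_theoretical"]

CRITERIA = ("temperature", "precipitation", "ph", "texture", "elevation", "climate_zone")

#: default lower altitude bound when a species record gives none
ALT_MIN_DEFAULT = -500.0


@dataclass(frozen=True)
class MatchConfig:
    temp_screen: str = "annual"        # "annual" | "monthly_extremes"
    alt_min_default: float = ALT_MIN_DEFAULT


@dataclass(frozen=True)
class MatchResult:
    region_id: int
    gez_id: int
    taxon: str
    matched: bool
    failed_criteria: tuple[str, ...]
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.evaluable and self.matched != (len(self.failed_criteria) == 0):
            raise ValueError("matched must mirror an empty failed-criteria list")


def is_match(species: SpeciesRecord, area: TargetArea,
             config: MatchConfig = MatchConfig()) -> MatchResult:
    """Test all six pedoclimatic criteria for one species × area pair.

    An area with a missing tested attribute yields an explicit unevaluable
    result (never a silent non-match).
    """
    tested_attrs = {"temperature": "temp", "precipitation": "prec", "ph": "ph",
                    "texture": "texture", "elevation": "elevation_m"}
    missing = [c for c, attr in tested_attrs.items() if attr in area.missing]
    if missing or not area.usable:
        return MatchResult(area.region_id, area.gez_id, species.taxon,
                           matched=False, evaluable=False,
                           failed_criteria=tuple(f"unevaluable:{m}" for m in
                                                 (missing or area.missing)))
    failed: list[str] = []

    if config.temp_screen == "monthly_extremes":
        t_ok = species.temp_abs[0] <= min(area.temp_monthly) and \
            max(area.temp_monthly) <= species.temp_abs[1]
    else:
        t_ok = species.temp_abs[0] <= area.mean_annual_temp <= species.temp_abs[1]
    if not t_ok:
        failed.append("temperature")

    if not species.prec_abs[0] <= area.annual_precipitation <= species.prec_abs[1]:
        failed.append("precipitation")
    if not species.ph_abs[0] <= area.ph <= species.ph_abs[1]:
        failed.append("ph")
    if area.texture not in species.texture_ok:
        failed.append("texture")
    alt_lo = species.alt_abs[0] if np.isfinite(species.alt_abs[0]) else config.alt_min_default
    if not alt_lo <= area.elevation_m <= species.alt_abs[1]:
        failed.append("elevation")
    if area.gez_id not in species.gez_ok:
        failed.append("climate_zone")

    return MatchResult(area.region_id, area.gez_id, species.taxon,
                       matched=not failed, failed_criteria=tuple(failed))


def match_all(species: list[SpeciesRecord], areas: list[TargetArea],
              config: MatchConfig = MatchConfig()) -> list[MatchResult]:
    """Evaluate every species against every area (|species| × |areas|
    results, identical to the brute-force double loop by construction)."""
    if not species or not areas:
        raise ValueError("need at least one species and one target area")
    return [is_match(sp, ar, config) for ar in areas for sp in species]


def count_theoretical(n_areas: int, n_species: int) -> int:
    """Number of theoretically possible area × species combinations."""
    if n_areas < 0 or n_species < 0:
        raise ValueError("counts must be non-negative")
    return n_areas * n_species


def matches_to_frame(results: list[MatchResult]) -> pd.DataFrame:
    """Diagnostic-friendly table with one boolean column per criterion."""
    rows = []
    for r in results:
        row = {"region_id": r.region_id, "gez_id": r.gez_id, "taxon": r.taxon,
               "matched": r.matched, "evaluable": r.evaluable}
        for c in CRITERIA:
            row[f"ok_{c}"] = r.evaluable and c not in r.failed_criteria
        rows.append(row)
    return pd.DataFrame(rows)
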