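"""Consolidation of marginal cells into characterized target areas.

Every retained marginal cell is labelled with its world region and FAO
Global Ecological Zone (GEZ), then all cells sharing a (region, GEZ) pair
are collapsed into one :class:`TargetArea`: continuous attributes become
area-weighted means, soil texture becomes the area-weighted mode, and the
area is the sum of the (latitude-dependent) cell areas. Monthly climate
normals are kept as 12-value vectors because the turnover model steps
monthly.

Water (90) and polar (50) GEZ codes are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import RasterLayer, cell_area_ha, combine_zone_codes, split_zone_code, zonal_aggregate
from .marginal_land import MarginalLandMask

__all__ = ["TargetArea", "assign_zones", "consolidate_target_areas", "summarize_areas",
           "target_areas_to_frame", "target_areas_from_frame"]

#: GEZ codes excluded from consolidation (water and polar)
EXCLUDED_GEZ_DEFAULT = frozenset({50, 90})

TEXTURE_CODES = {1: "coarse", 2: "medium", 3: "fine"}
TEXTURE_NAMES = {v: k for k, v in TEXTURE_CODES.items()}

MONTH_COLS = [f"m{i:02d}" for i in range(1, 13)]


@dataclass
class TargetArea:
    """One consolidated region × GEZ unit of marginal land."""

    region_id: int
    gez_id: int
    area_ha: float
    temp_monthly: list[float]   # °C
    prec_monthly: list[float]   # mm per month
    pet_monthly: list[float]    # mm per month
    clay_pct: float
    ph: float
    texture: str                # coarse | medium | fine
    bulk_density: float         # Mg m⁻³
    soil_depth_cm: float
    elevation_m: float
    slope_pct: float
    soil_loss: float            # Mg soil ha⁻¹ yr⁻¹
    soc_init: float             # Mg C ha⁻¹
    usable: bool = True
    missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("target area must have positive area")
        for name in ("temp_monthly", "prec_monthly", "pet_monthly"):
            v = getattr(self, name)
            if v is not None and len(v) != 12:
                raise ValueError(f"{name} must have 12 entries")

    @property
    def mean_annual_temp(self) -> float:
        return float(np.mean(self.temp_monthly))

    @property
    def annual_precipitation(self) -> float:
        return float(np.sum(self.prec_monthly))

    @property
    def key(self) -> tuple[int, int]:
        return (self.region_id, self.gez_id)


def assign_zones(
    mask: MarginalLandMask | np.ndarray,
    regions: RasterLayer,
    gez: RasterLayer,
    excluded_gez: Iterable[int] = EXCLUDED_GEZ_DEFAULT,
):
    """Label each retained cell with its (region, GEZ) pair.

    Returns ``(zone_raster, n_dropped)`` where the zone raster holds the
    combined code on retained cells and nodata elsewhere; cells with a
    missing region or GEZ id (or an excluded GEZ) are dropped and counted.
    """
    m = mask.mask if isinstance(mask, MarginalLandMask) else np.asarray(mask, dtype=bool)
    zones = combine_zone_codes(regions, gez)
    excluded = np.isin(np.asarray(gez.values), list(excluded_gez))
    ok = m & zones.valid_mask() & ~excluded
    dropped = int(m.sum() - ok.sum())
    coded = np.where(ok, zones.values, zones.nodata)
    return zones.with_values(coded), dropped


def consolidate_target_areas(
    mask: MarginalLandMask | np.ndarray,
    zone_raster: RasterLayer,
    climate: Mapping[str, Sequence[RasterLayer]],
    soil: Mapping[str, RasterLayer],
    terrain: Mapping[str, RasterLayer],
    soil_loss: RasterLayer,
    soc: RasterLayer,
    min_area_ha: float = 0.0,
) -> list[TargetArea]:
    """Collapse labelled marginal cells into TargetArea records.

    ``climate`` maps ``temp``/``prec``/``pet`` to 12 monthly rasters;
    ``soil`` maps ``clay_pct``/``ph``/``texture``/``bulk_density``/
    ``soil_depth_cm`` and ``terrain`` maps ``elevation_m``/``slope_pct`` to
    single rasters. A zone where a required attribute is entirely missing
    keeps its record but is flagged unusable for matching.
    """
    m = mask.mask if isinstance(mask, MarginalLandMask) else np.asarray(mask, dtype=bool)
    areas_grid = cell_area_ha(zone_raster)
    zvals = np.asarray(zone_raster.values)
    retained = m & zone_raster.valid_mask()
    if not retained.any():
        raise ValueError("no retained cells to consolidate")

    masked_zone = zone_raster.with_values(np.where(retained, zvals, zone_raster.nodata))

    def agg(layer: RasterLayer, stat: str) -> pd.Series:
        df = zonal_aggregate(layer, masked_zone, stat, weights=areas_grid)
        return df[stat]

    area_by_zone = zonal_aggregate(
        RasterLayer(np.ones(m.shape), zone_raster.transform, zone_raster.crs, -1.0),
        masked_zone, "sum", weights=areas_grid)["sum"]

    columns: dict[str, pd.Series] = {}
    scalar_specs = {
        "clay_pct": (soil["clay_pct"], "mean"),
        "ph": (soil["ph"], "mean"),
        "texture": (soil["texture"], "mode"),
        "bulk_density": (soil["bulk_density"], "mean"),
        "soil_depth_cm": (soil["soil_depth_cm"], "mean"),
        "elevation_m": (terrain["elevation_m"], "mean"),
        "slope_pct": (terrain["slope_pct"], "mean"),
        "soil_loss": (soil_loss, "mean"),
        "soc_init": (soc, "mean"),
    }
    for name, (layer, stat) in scalar_specs.items():
        columns[name] = agg(layer, stat)
    monthly: dict[str, list[pd.Series]] = {}
    for var in ("temp", "prec", "pet"):
        layers = climate[var]
        if len(layers) != 12:
            raise ValueError(f"climate[{var!r}] must have 12 monthly layers")
        monthly[var] = [agg(layer, "mean") for layer in layers]

    out: list[TargetArea] = []
    for code, area_ha in area_by_zone.sort_index().items():
        if area_ha < min_area_ha:
            continue
        region_id, gez_id = split_zone_code(code)
        missing = [n for n, s in columns.items() if code not in s.index]
        vals = {n: float(s.get(code, np.nan)) for n, s in columns.items()}
        clim = {}
        for var in ("temp", "prec", "pet"):
            vec = [float(s.get(code, np.nan)) for s in monthly[var]]
            if any(np.isnan(vec)):
                missing.append(var)
            clim[var] = vec
        texture = TEXTURE_CODES.get(int(vals["texture"]) if not np.isnan(vals["texture"]) else -1, "")
        if not texture:
            missing.append("texture")
        out.append(TargetArea(
            region_id=region_id, gez_id=gez_id, area_ha=float(area_ha),
            temp_monthly=clim["temp"], prec_monthly=clim["prec"], pet_monthly=clim["pet"],
            clay_pct=vals["clay_pct"], ph=vals["ph"], texture=texture,
            bulk_density=vals["bulk_density"], soil_depth_cm=vals["soil_depth_cm"],
            elevation_m=vals["elevation_m"], slope_pct=vals["slope_pct"],
            soil_loss=vals["soil_loss"], soc_init=vals["soc_init"],
            usable=not missing, missing=sorted(set(missing)),
        ))
    return out


def summarize_areas(areas: list[TargetArea], reference_mha: float | None = None) -> dict:
    """Totals in Mha per region, per GEZ and overall, with optional share of
    a reference extent (e.g. all SOC-deficient marginal land)."""
    if not areas:
        raise ValueError("no target areas to summarize")
    df = pd.DataFrame({
        "region_id": [a.region_id for a in areas],
        "gez_id": [a.gez_id for a in areas],
        "mha": [a.area_ha / 1e6 for a in areas],
    })
    total = float(df["mha"].sum())
    by_region = df.groupby("region_id")["mha"].sum()
    by_gez = df.groupby("gez_id")["mha"].sum()
    out = {
        "total_mha": total,
        "n_target_areas": len(areas),
        "by_region_mha": by_region,
        "by_gez_mha": by_gez,
        "by_region_pct": 100.0 * by_region / total,
        "by_gez_pct": 100.0 * by_gez / total,
    }
    if reference_mha:
        out["share_of_reference_pct"] = 100.0 * total / reference_mha
    return out


def target_areas_to_frame(areas: list[TargetArea]) -> pd.DataFrame:
    """Serialize target areas to a flat table (monthly vectors as 12
    suffixed columns per variable)."""
    rows = []
    for a in areas:
        row = {k: v for k, v in asdict(a).items()
               if k not in ("temp_monthly", "prec_monthly", "pet_monthly", "missing")}
        row["missing"] = "|".join(a.missing)
        for var, vec in (("temp", a.temp_monthly), ("prec", a.prec_monthly), ("pet", a.pet_monthly)):
            for col, v in zip(MONTH_COLS, vec):
                row[f"{var}_{col}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def target_areas_from_frame(df: pd.DataFrame) -> list[TargetArea]:
    out = []
    for _, row in df.iterrows():
        out.append(TargetArea(
            region_id=int(row["region_id"]), gez_id=int(row["gez_id"]),
            area_ha=float(row["area_ha"]),
            temp_monthly=[float(row[f"temp_{c}"]) for c in MONTH_COLS],
            prec_monthly=[float(row[f"prec_{c}"]) for c in MONTH_COLS],
            pet_monthly=[float(row[f"pet_{c}"]) for c in MONTH_COLS],
            clay_pct=float(row["clay_pct"]), ph=float(row["ph"]),
            texture=str(row["texture"]), bulk_density=float(row["bulk_density"]),
            soil_depth_cm=float(row["soil_depth_cm"]), elevation_m=float(row["elevation_m"]),
            slope_pct=float(row["slope_pct"]), soil_loss=float(row["soil_loss"]),
            soc_init=float(row["soc_init"]), usable=bool(row.get("usable", True)),
            missing=[s for s in str(row.get("missing", "")).split("|") if s and s != "nan"],
        ))
    return out
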