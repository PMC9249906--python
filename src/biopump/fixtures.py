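"""Deterministic synthetic world with machine-readable ground truth.

The generator plants known numbers of bare, sparsely vegetated and
abandoned-cropland cells on a toy geographic grid, then removes known
subsets through each downstream filter (SOC above threshold, protected
area, severe problem land). Regions are vertical bands, ecological zones
horizontal bands, and every pedoclimatic attribute is constant within its
band — so zonal aggregates are exact and the expected match matrix can be
derived by the generator's own independent comparison loops.

Erosion outcomes are engineered to be decidable by construction: benign
zones get soil-loss rates low enough that every matched pair stays
net-positive, while one designated stress zone gets a soil-loss rate so
large that cumulative erosion must exceed any attainable final stock
(the bound uses the never-decaying inert pool as a floor on the eroded
series and total mass balance as a ceiling on the final stock). The
stress rate is a correctness device, not a calibration of real erosion.

Everything is a pure function of (config, seed); the same pair always
reproduces bit-identical rasters and ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geodata import GridTransform, RasterLayer, write_raster
from .consolidate import TEXTURE_CODES

__all__ = ["WorldConfig", "SyntheticWorld", "make_synthetic_world",
           "make_species_panel", "make_climate", "write_world"]

CRS = "EPSG:4326"

# land-cover codes used on the toy grid (ESA-CCI-style legend)
LC_CROPLAND, LC_GRASSLAND, LC_SPARSE, LC_BARE, LC_FOREST = 10, 130, 150, 200, 60

GOOD = "good"
STRESS = "stress"


@dataclass(frozen=True)
class WorldConfig:
    size: int = 100
    n_regions: int = 4
    gez_ids: tuple[int, ...] = (13, 23, 33, 41)
    stress_gez: int = 41           # the erosion-dominated zone
    n_bare: int = 400
    n_sparse: int = 150
    n_abandoned: int = 30          # cropland → grassland transitions
    n_abandoned_bare: int = 10     # cropland → bare (provenance precedence)
    n_soc_kill: int = 30           # candidates pushed above the SOC threshold
    n_protected_kill: int = 25
    n_problem_kill: int = 20
    n_zone_drop: int = 0           # marginal cells given a missing region id
    soc_threshold: float = 50.0
    soc_range: tuple[float, float] = (15.0, 45.0)
    # per-region attribute bands (cycled if n_regions differs)
    ph_by_region: tuple[float, ...] = (5.0, 6.5, 7.5, 8.2)
    elev_by_region: tuple[float, ...] = (200.0, 400.0, 600.0, 2500.0)
    clay_by_region: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0)
    # per-GEZ attribute bands
    temp_mean_by_gez: tuple[float, ...] = (26.0, 18.0, 9.0, 2.0)
    temp_amp_by_gez: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0)
    prec_mean_by_gez: tuple[float, ...] = (80.0, 50.0, 45.0, 40.0)
    prec_amp_by_gez: tuple[float, ...] = (30.0, 15.0, 10.0, 8.0)
    pet_mean_by_gez: tuple[float, ...] = (100.0, 90.0, 60.0, 30.0)
    texture_by_gez: tuple[int, ...] = (2, 1, 2, 3)
    soil_loss_by_gez: tuple[float, ...] = (1.0, 1.2, 0.8, 50_000.0)
    bulk_density: float = 1.4
    soil_depth_cm: float = 30.0
    slope_pct: float = 5.0
    climate_noise: float = 0.0
    cell_deg: float = 0.01
    lat_top: float = 1.0
    lon_left: float = 10.0

    def __post_init__(self) -> None:
        if self.size < 4:
            raise ValueError("grid must be at least 4×4")
        if self.n_regions < 1 or not self.gez_ids:
            raise ValueError("need at least one region and one GEZ")
        planted = self.n_bare + self.n_sparse + self.n_abandoned + self.n_abandoned_bare
        if planted > self.size * self.size:
            raise ValueError("more planted cells than grid cells")
        kills = self.n_soc_kill + self.n_protected_kill + self.n_problem_kill + self.n_zone_drop
        if kills > self.n_bare:
            raise ValueError("filter kills must fit inside the planted bare cells")
        if self.stress_gez not in self.gez_ids:
            raise ValueError("stress GEZ must be one of the GEZ bands")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    rasters: dict[str, RasterLayer]
    climate: dict[int, dict[str, np.ndarray]]   # gez → temp/prec/pet 12-vectors
    climate_rasters: dict[str, list[RasterLayer]]
    species: pd.DataFrame
    ground_truth: dict


def _bands(size: int, n: int, axis: int) -> np.ndarray:
    """Band index grid (0..n-1): vertical bands for axis=1, horizontal for 0."""
    idx = np.minimum((np.arange(size) * n) // size, n - 1)
    return np.broadcast_to(idx[None, :] if axis == 1 else idx[:, None], (size, size)).copy()


def make_climate(config: WorldConfig, seed: int) -> dict[int, dict[str, np.ndarray]]:
    """Sinusoidal 12-month normals per GEZ band (seeded noise optional)."""
    rng = np.random.default_rng(seed + 1)
    months = np.arange(12)
    wave = np.sin(2 * np.pi * months / 12)
    out: dict[int, dict[str, np.ndarray]] = {}
    for i, gez in enumerate(config.gez_ids):
        j = i % len(config.temp_mean_by_gez)
        noise = lambda: rng.normal(0.0, config.climate_noise, 12) if config.climate_noise else 0.0
        out[gez] = {
            "temp": config.temp_mean_by_gez[j] + config.temp_amp_by_gez[j] * wave + noise(),
            "prec": np.clip(config.prec_mean_by_gez[j] + config.prec_amp_by_gez[j] * wave + noise(), 0, None),
            "pet": np.full(12, config.pet_mean_by_gez[j]) + noise(),
        }
    return out


def _species_specs(config: WorldConfig) -> list[dict]:
    all_gez = list(config.gez_ids)
    return [
        dict(name="pangrass", taxon="Panicum universale", life_form="grass",
             lifecycle="annual", lifetime_yr=1, temp=(-5, 40), prec=(0, 5000),
             ph=(3.0, 10.0), texture="coarse|medium|fine", alt=(-500, 5000),
             gez=all_gez, dm=(0.0, 4.0, 0.0, 1.0), c=(0.45, 0.45, 0.45, 0.45),
             ret=(0.0, 1.0, 0.0), deciduous=False, cover=0.30),
        dict(name="acidgrain", taxon="Secale acidophilum", life_form="crop",
             lifecycle="annual", lifetime_yr=1, temp=(5, 35), prec=(300, 2000),
             ph=(4.0, 6.6), texture="coarse|medium", alt=(0, 1000),
             gez=[g for g in all_gez if g != config.stress_gez],
             dm=(2.0, 3.0, 1.0, 1.2), c=(0.45, 0.45, 0.40, 0.45),
             ret=(0.0, 0.8, 1.0), deciduous=False, cover=0.45),
        dict(name="tropicwood", taxon="Melia synthetica", life_form="tree",
             lifecycle="perennial", lifetime_yr=20, temp=(20, 35), prec=(500, 3000),
             ph=(4.5, 8.5), texture="medium|fine", alt=(-500, 3000),
             gez=[all_gez[0]], dm=(10.0, 40.0, 2.0, 20.0), c=(0.5, 0.5, 0.5, 0.5),
             ret=(0.0, 0.5, 1.0), deciduous=True, cover=0.20),
        dict(name="highsteppe", taxon="Festuca montana", life_form="grass",
             lifecycle="perennial", lifetime_yr=5, temp=(-10, 15), prec=(200, 1000),
             ph=(6.0, 9.0), texture="medium|fine", alt=(2000, 5000),
             gez=all_gez[2:], dm=(0.0, 17.5, 0.0, 5.0), c=(0.42, 0.42, 0.42, 0.42),
             ret=(0.0, 1.0, 0.0), deciduous=False, cover=0.35),
        dict(name="nomatch", taxon="Calluna acerrima", life_form="crop",
             lifecycle="annual", lifetime_yr=1, temp=(5, 30), prec=(300, 2000),
             ph=(2.0, 2.5), texture="coarse|medium|fine", alt=(-500, 5000),
             gez=all_gez, dm=(1.0, 1.5, 0.5, 1.0), c=(0.45, 0.45, 0.45, 0.45),
             ret=(0.0, 1.0, 1.0), deciduous=False, cover=0.25),
    ]


def make_species_panel(config: WorldConfig, seed: int):
    """Species trait table plus the expected match outcome per criterion.

    Returns ``(frame, specs)``; the expected match matrix itself is derived
    in :func:`make_synthetic_world` against the occupied zones.
    """
    specs = _species_specs(config)
    rows = []
    for s in specs:
        rows.append({
            "name": s["name"], "taxon": s["taxon"], "life_form": s["life_form"],
            "lifecycle": s["lifecycle"], "lifetime_yr": s["lifetime_yr"],
            "temp_min": s["temp"][0], "temp_max": s["temp"][1],
            "prec_min": s["prec"][0], "prec_max": s["prec"][1],
            "ph_min": s["ph"][0], "ph_max": s["ph"][1],
            "texture_ok": s["texture"], "alt_min": s["alt"][0], "alt_max": s["alt"][1],
            "gez_ok": "|".join(str(g) for g in s["gez"]),
            "dm_product": s["dm"][0], "dm_stem": s["dm"][1],
            "dm_leaf": s["dm"][2], "dm_root": s["dm"][3],
            "c_product": s["c"][0], "c_stem": s["c"][1],
            "c_leaf": s["c"][2], "c_root": s["c"][3],
            "ret_product": s["ret"][0], "ret_stem": s["ret"][1], "ret_leaf": s["ret"][2],
            "deciduous": s["deciduous"], "cover_factor": s["cover"],
            "cover_months": "|".join(str(m) for m in range(1, 13)),
        })
    return pd.DataFrame(rows), specs


def _expected_match(spec: dict, zone_attrs: dict) -> bool:
    """Generator-side re-derivation of the matching decision (independent
    simple comparisons against the planned band attributes)."""
    t = zone_attrs["mean_annual_temp"]
    p = zone_attrs["annual_prec"]
    return (
        spec["temp"][0] <= t <= spec["temp"][1]
        and spec["prec"][0] <= p <= spec["prec"][1]
        and spec["ph"][0] <= zone_attrs["ph"] <= spec["ph"][1]
        and zone_attrs["texture"] in spec["texture"].split("|")
        and spec["alt"][0] <= zone_attrs["elev"] <= spec["alt"][1]
        and zone_attrs["gez"] in spec["gez"]
    )


def make_synthetic_world(config: WorldConfig = WorldConfig(), seed: int = 0) -> SyntheticWorld:
    """Build the full synthetic world (rasters, climate, species, truth)."""
    rng = np.random.default_rng(seed)
    n = config.size
    t = GridTransform(x0=config.lon_left, y0=config.lat_top, dx=config.cell_deg, dy=config.cell_deg)

    def layer(values, kind="continuous", nodata=-9999.0):
        return RasterLayer(np.asarray(values), t, CRS, nodata, kind)

    region_band = _bands(n, config.n_regions, axis=1)
    gez_band = _bands(n, len(config.gez_ids), axis=0)
    regions = region_band + 1
    gez = np.array(config.gez_ids)[gez_band]

    # --- plant marginal cells -------------------------------------------
    flat = rng.permutation(n * n)
    counts = [config.n_bare, config.n_sparse, config.n_abandoned, config.n_abandoned_bare]
    splits = np.split(flat, np.cumsum(counts))[:4]
    bare_idx, sparse_idx, aband_idx, aband_bare_idx = (np.sort(s) for s in splits)

    lc_t1 = np.full((n, n), LC_FOREST)
    lc_t0 = np.full((n, n), LC_FOREST)
    for idx, code in ((bare_idx, LC_BARE), (sparse_idx, LC_SPARSE)):
        lc_t1.flat[idx] = code
        lc_t0.flat[idx] = code
    lc_t0.flat[aband_idx] = LC_CROPLAND
    lc_t1.flat[aband_idx] = LC_GRASSLAND     # abandoned but not a candidate cover
    lc_t0.flat[aband_bare_idx] = LC_CROPLAND
    lc_t1.flat[aband_bare_idx] = LC_BARE     # abandoned AND bare → abandoned wins

    # --- filter kills drawn from the planted bare cells -----------------
    kill_pool = rng.permutation(bare_idx)
    k1, k2, k3, k4 = config.n_soc_kill, config.n_protected_kill, config.n_problem_kill, config.n_zone_drop
    soc_kill = kill_pool[:k1]
    prot_kill = kill_pool[k1:k1 + k2]
    prob_kill = kill_pool[k1 + k2:k1 + k2 + k3]
    zone_drop = kill_pool[k1 + k2 + k3:k1 + k2 + k3 + k4]

    lo, hi = config.soc_range
    soc = rng.uniform(5.0, 60.0, (n, n))
    marginal_all = np.concatenate([bare_idx, sparse_idx, aband_idx, aband_bare_idx])
    soc.flat[marginal_all] = rng.uniform(lo, hi, marginal_all.size)
    soc.flat[soc_kill] = config.soc_threshold + 5.0

    protected = np.zeros((n, n), dtype=np.int64)
    protected.flat[prot_kill] = 1
    problem = np.zeros((n, n), dtype=np.int64)
    problem.flat[prob_kill] = 3  # steep terrain, a severe code

    regions_full = regions.astype(float)
    regions_full.flat[zone_drop] = -9999.0

    # --- band attributes -------------------------------------------------
    def by_region(vals):
        v = np.array([vals[i % len(vals)] for i in range(config.n_regions)])
        return v[region_band]

    def by_gez(vals):
        v = np.array([vals[i % len(vals)] for i in range(len(config.gez_ids))])
        return v[gez_band]

    climate = make_climate(config, seed)
    climate_rasters: dict[str, list[RasterLayer]] = {}
    for var in ("temp", "prec", "pet"):
        climate_rasters[var] = [
            layer(np.array([climate[g][var][m] for g in config.gez_ids])[gez_band])
            for m in range(12)
        ]

    rasters = {
        "lc_t0": layer(lc_t0, "categorical", -1),
        "lc_t1": layer(lc_t1, "categorical", -1),
        "soc": layer(soc),
        "protected": layer(protected, "categorical", -1),
        "problem": layer(problem, "categorical", -1),
        "regions": layer(regions_full, "categorical"),
        "gez": layer(gez, "categorical", -1),
        "clay_pct": layer(by_region(config.clay_by_region)),
        "ph": layer(by_region(config.ph_by_region)),
        "texture": layer(by_gez(config.texture_by_gez), "categorical", -1),
        "bulk_density": layer(np.full((n, n), config.bulk_density)),
        "soil_depth_cm": layer(np.full((n, n), config.soil_depth_cm)),
        "elevation_m": layer(by_region(config.elev_by_region)),
        "slope_pct": layer(np.full((n, n), config.slope_pct)),
        "soil_loss": layer(by_gez(config.soil_loss_by_gez)),
    }

    # --- ground truth by set arithmetic ----------------------------------
    killed = set(soc_kill) | set(prot_kill) | set(prob_kill)
    surv_bare = [i for i in bare_idx if i not in killed]
    surv = {
        "bare": surv_bare,
        "sparse": list(sparse_idx),
        "abandoned": list(aband_idx) + list(aband_bare_idx),
    }
    zone_dropped = set(zone_drop)
    occupied: set[tuple[int, int]] = set()
    for cells in surv.values():
        for i in cells:
            if i in zone_dropped:
                continue
            r, c = divmod(int(i), n)
            occupied.add((int(regions[r, c]), int(gez[r, c])))

    species_df, specs = make_species_panel(config, seed)
    zone_attrs = {}
    for reg_id, gez_id in sorted(occupied):
        gi = config.gez_ids.index(gez_id)
        ri = reg_id - 1
        zone_attrs[(reg_id, gez_id)] = {
            "gez": gez_id,
            "mean_annual_temp": float(np.mean(climate[gez_id]["temp"])),
            "annual_prec": float(np.sum(climate[gez_id]["prec"])),
            "ph": config.ph_by_region[ri % len(config.ph_by_region)],
            "texture": TEXTURE_CODES[config.texture_by_gez[gi % len(config.texture_by_gez)]],
            "elev": config.elev_by_region[ri % len(config.elev_by_region)],
        }
    match_matrix = {
        f"{reg}:{gz}:{s['taxon']}": _expected_match(s, attrs)
        for (reg, gz), attrs in zone_attrs.items() for s in specs
    }
    viable = sum(match_matrix.values())
    good_zone_matches = sum(
        ok for key, ok in match_matrix.items()
        if int(key.split(":")[1]) != config.stress_gez
    )
    good_zones_with_match = {
        tuple(map(int, key.split(":")[:2]))
        for key, ok in match_matrix.items()
        if ok and int(key.split(":")[1]) != config.stress_gez
    }
    matched_taxa = {key.split(":")[2] for key, ok in match_matrix.items() if ok}

    ground_truth = {
        "marginal_cells": {k: len(v) for k, v in surv.items()}
        | {"total": sum(len(v) for v in surv.values())},
        "zone_dropped": int(len(zone_dropped)),
        "n_target_areas": len(occupied),
        "occupied_zones": sorted(list(z) for z in occupied),
        "n_species": len(specs),
        "theoretical_matches": len(occupied) * len(specs),
        "viable_matches": int(viable),
        "matched_species": len(matched_taxa),
        "net_positive_pairs": int(good_zone_matches),
        "best_cases": len(good_zones_with_match),
        "match_matrix": match_matrix,
    }
    return SyntheticWorld(config=config, seed=seed, rasters=rasters,
                          climate=climate, climate_rasters=climate_rasters,
                          species=species_df, ground_truth=ground_truth)


def write_world(world: SyntheticWorld, outdir) -> Path:
    """Write the world to disk in the real input formats (.asc rasters,
    species CSV, climate CSV, ground-truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, r in world.rasters.items():
        write_raster(r, outdir / f"{name}.asc")
    for var, layers in world.climate_rasters.items():
        for m, r in enumerate(layers, start=1):
            write_raster(r, outdir / f"climate_{var}_{m:02d}.asc")
    world.species.to_csv(outdir / "species.csv", index=False)
    clim_rows = [{"gez_id": g, "var": var, **{f"m{m:02d}": float(v[m - 1]) for m in range(1, 13)}}
                 for g, d in world.climate.items() for var, v in d.items()]
    pd.DataFrame(clim_rows).to_csv(outdir / "climate.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(world.ground_truth, fh, indent=1, default=str)
    return outdir
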