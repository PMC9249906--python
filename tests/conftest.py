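import numpy as np
import pytest

from biopump.consolidate import TargetArea
from biopump.fixtures import WorldConfig, make_synthetic_world
from biopump.geodata import GridTransform, RasterLayer
from biopump.plants import SpeciesRecord


@pytest.fixture
def grid_transform():
    return GridTransform(x0=10.0, y0=1.0, dx=0.01, dy=0.01)


@pytest.fixture
def make_layer(grid_transform):
    def _make(values, kind="continuous", nodata=-9999.0, crs="EPSG:4326"):
        return RasterLayer(np.asarray(values, dtype=float), grid_transform, crs, nodata, kind)
    return _make


@pytest.fixture(scope="session")
def small_world():
    cfg = WorldConfig(size=30, n_bare=60, n_sparse=20, n_abandoned=8,
                      n_abandoned_bare=4, n_soc_kill=6, n_protected_kill=5,
                      n_problem_kill=4)
    return make_synthetic_world(cfg, seed=7)


@pytest.fixture(scope="session")
def default_world():
    return make_synthetic_world(WorldConfig(), seed=11)


@pytest.fixture(scope="session")
def default_pipeline(default_world):
    from biopump.pipeline import run_pipeline

    return run_pipeline(default_world.rasters, default_world.climate_rasters,
                        default_world.species)


def make_area(**overrides) -> TargetArea:
    base = dict(
        region_id=1, gez_id=13, area_ha=1000.0,
        temp_monthly=[26.0] * 12, prec_monthly=[80.0] * 12, pet_monthly=[100.0] * 12,
        clay_pct=20.0, ph=6.5, texture="medium", bulk_density=1.4,
        soil_depth_cm=30.0, elevation_m=200.0, slope_pct=5.0,
        soil_loss=2.0, soc_init=30.0,
    )
    base.update(overrides)
    return TargetArea(**base)


def make_species(**overrides) -> SpeciesRecord:
    base = dict(
        name="testgrass", taxon="Poa exempli", life_form="grass", lifecycle="annual",
        lifetime_yr=1.0, temp_abs=(-5.0, 40.0), prec_abs=(0.0, 5000.0),
        ph_abs=(3.0, 10.0), texture_ok=frozenset({"coarse", "medium", "fine"}),
        alt_abs=(-500.0, 5000.0), gez_ok=frozenset({13, 23, 33, 41}),
        frac_dm={"product": 0.0, "stem": 4.0, "leaf": 0.0, "root": 1.0},
        c_content={"product": 0.45, "stem": 0.45, "leaf": 0.45, "root": 0.45},
        soil_return={"product": 0.0, "stem": 1.0, "leaf": 0.0},
        deciduous=False, cover_factor=0.3,
    )
    base.update(overrides)
    return SpeciesRecord(**base)
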