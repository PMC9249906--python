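"""Scenario orchestration: simulate matched pairs, net out erosion, pick
best cases and derive summary statistics.

For every matched species × target-area pair the workflow is: initialize
the five carbon pools from the area's measured stock, run the monthly
turnover model over the 2020–2100 horizon (80 years of recycled climate
normals), erode annually against the simulated trajectory, and report the
net stock — final SOC prior to erosion minus cumulative eroded SOC. A pair
is net-positive when that difference exceeds zero; for each target area
the net-positive pair with the highest net stock is the "best case".

Statistical comparison of initial vs final stocks over the best cases uses
a two-sided paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .consolidate import TargetArea
from .match_engine import MatchResult, count_theoretical
from .plants import SpeciesRecord, annual_c_input
from . import soc_rothc
from .soc_rothc import DPM_RPM_BY_LIFE_FORM, RothCParams, DEFAULT_PARAMS
from . import soc_erosion as erosion_mod
from .soc_erosion import C_REF_DEFAULT, adjust_soil_loss, cumulative_erosion

__all__ = [
    "SimConfig", "SimulationResult", "simulate_pair", "simulate_matched",
    "select_best_case", "paired_t_test", "annualize", "report", "share_pct",
]

HORIZON_START = 2020
HORIZON_END = 2100
HORIZON_YEARS = HORIZON_END - HORIZON_START  # 80


@dataclass(frozen=True)
class SimConfig:
    years: int = HORIZON_YEARS
    params: RothCParams = DEFAULT_PARAMS
    c_ref: float = C_REF_DEFAULT
    enrichment: float = 1.0
    root_multiplier: float = 1.0
    pan_correction: bool = False
    erosion_coupling: str = "offline"   # "offline" | "online"


@dataclass(frozen=True)
class SimulationResult:
    region_id: int
    gez_id: int
    taxon: str
    soc_init: float
    soc_final: float       # prior to erosion
    eroded_cum: float
    net_soc: float
    net_positive: bool
    annualized_net: float
    initial_loss_flag: bool
    annual_c_input: float

    def __post_init__(self) -> None:
        if not math.isclose(self.net_soc, self.soc_final - self.eroded_cum,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("net SOC must equal final SOC minus cumulative erosion")


def _monthly_input(annual_c: float) -> np.ndarray:
    # plant inputs spread evenly over the year
    return np.full(12, annual_c / 12.0)


def simulate_pair(area: TargetArea, species: SpeciesRecord,
                  config: SimConfig = SimConfig()) -> SimulationResult:
    """Run the coupled turnover + erosion simulation for one matched pair."""
    params = config.params
    profile = annual_c_input(species, config.root_multiplier)
    ratio = species.dpm_rpm_ratio or DPM_RPM_BY_LIFE_FORM[species.life_form]
    covered = np.array([m in species.cover_months for m in range(1, 13)])
    state0 = soc_rothc.init_pools(area.soc_init, area.clay_pct, params)
    e_adj = adjust_soil_loss(area.soil_loss, species.cover_factor, config.c_ref)

    if config.erosion_coupling == "online":
        soc_final, eroded = _run_online(area, species, state0, profile.annual_c,
                                        ratio, covered, e_adj, config)
    else:
        traj = soc_rothc.run_rothc(
            state0, area.temp_monthly, area.prec_monthly, area.pet_monthly,
            _monthly_input(profile.annual_c), covered, config.years,
            area.clay_pct, area.soil_depth_cm, ratio, params,
            pan_correction=config.pan_correction)
        yearly = traj.loc[traj["month"] % 12 == 0, "total"].to_numpy()  # incl. year 0
        soc_final = float(yearly[-1])
        res = cumulative_erosion(yearly[1:], e_adj, area.bulk_density,
                                 area.soil_depth_cm, config.years, config.enrichment)
        eroded = res.cumulative

    net = soc_final - eroded
    return SimulationResult(
        region_id=area.region_id, gez_id=area.gez_id, taxon=species.taxon,
        soc_init=area.soc_init, soc_final=soc_final, eroded_cum=eroded,
        net_soc=net, net_positive=net > 0,
        annualized_net=net / config.years,
        initial_loss_flag=net > 0 and net < area.soc_init,
        annual_c_input=profile.annual_c,
    )


def _run_online(area, species, state0, annual_c, ratio, covered, e_adj, config):
    """Sensitivity mode: eroded carbon is removed proportionally from all
    pools at each year end instead of being bookkept outside the model."""
    params = config.params
    state = state0
    eroded = 0.0
    monthly = _monthly_input(annual_c)
    for year in range(config.years):
        traj = soc_rothc.run_rothc(
            state, area.temp_monthly, area.prec_monthly, area.pet_monthly,
            monthly, covered, 1, area.clay_pct, area.soil_depth_cm, ratio,
            params, pan_correction=config.pan_correction)
        last = traj.iloc[-1]
        state = soc_rothc.RothCState(
            dpm=last["dpm"], rpm=last["rpm"], bio=last["bio"],
            hum=last["hum"], iom=last["iom"], acc_tsmd=state.acc_tsmd)
        loss = erosion_mod.soc_erosion_annual(
            e_adj, state.total, area.bulk_density, area.soil_depth_cm, config.enrichment)
        loss = min(loss, state.total)
        frac = 1.0 - loss / state.total if state.total > 0 else 1.0
        state = soc_rothc.RothCState(
            dpm=state.dpm * frac, rpm=state.rpm * frac, bio=state.bio * frac,
            hum=state.hum * frac, iom=state.iom * frac, acc_tsmd=state.acc_tsmd)
        eroded += loss
    return state.total + eroded, eroded  # final prior to erosion ≡ total + removed


def simulate_matched(matches: list[MatchResult], areas: list[TargetArea],
                     species: list[SpeciesRecord],
                     config: SimConfig = SimConfig()) -> list[SimulationResult]:
    """Simulate every matched pair from a match table."""
    area_by_key = {a.key: a for a in areas}
    sp_by_taxon = {s.taxon: s for s in species}
    out = []
    for m in matches:
        if not m.matched:
            continue
        out.append(simulate_pair(area_by_key[(m.region_id, m.gez_id)],
                                 sp_by_taxon[m.taxon], config))
    return out


def select_best_case(results: list[SimulationResult]) -> pd.DataFrame:
    """One row per target area: the net-positive pair with the highest net
    SOC (ties broken by taxon name ascending). Areas with no net-positive
    pair are omitted."""
    best: dict[tuple[int, int], SimulationResult] = {}
    for r in sorted(results, key=lambda r: r.taxon):
        if not r.net_positive:
            continue
        key = (r.region_id, r.gez_id)
        if key not in best or r.net_soc > best[key].net_soc:
            best[key] = r
    rows = [{
        "region_id": r.region_id, "gez_id": r.gez_id, "taxon": r.taxon,
        "soc_init": r.soc_init, "soc_final": r.soc_final,
        "eroded_cum": r.eroded_cum, "net_soc": r.net_soc,
        "annualized_net": r.annualized_net,
        "erosion_share_of_final_pct": 100.0 * r.eroded_cum / r.soc_final
        if r.soc_final > 0 else np.nan,
        "initial_loss_flag": r.initial_loss_flag,
    } for r in sorted(best.values(), key=lambda r: (r.region_id, r.gez_id))]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTest:
    t: float
    p: float | None
    df: int
    degenerate: bool


def paired_t_test(initial, final) -> PairedTest:
    """Two-sided paired t-test on final − initial differences.

    Zero-variance differences make the statistic undefined; such inputs
    return a degenerate result with no p-value rather than an arbitrary
    number.
    """
    x = np.asarray(initial, dtype=float)
    y = np.asarray(final, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of at least 2 pairs")
    d = y - x
    if np.isclose(d.std(ddof=1), 0.0):
        return PairedTest(t=float("nan"), p=None, df=len(x) - 1, degenerate=True)
    res = stats.ttest_rel(y, x)
    return PairedTest(t=float(res.statistic), p=float(res.pvalue),
                      df=len(x) - 1, degenerate=False)


def annualize(cumulative: float, start_year: int, end_year: int) -> float:
    """Convert a cumulative stock change to a mean annual rate."""
    if end_year <= start_year:
        raise ValueError("end year must follow start year")
    return cumulative / (end_year - start_year)


def share_pct(numerator: float, denominator: float) -> int:
    """Percentage share rounded half-up to the nearest integer."""
    if denominator == 0:
        raise ValueError("zero denominator")
    pct = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def report(matches: list[MatchResult], results: list[SimulationResult],
           best: pd.DataFrame, *,
           n_areas: int, n_species: int,
           species_by_taxon: dict[str, SpeciesRecord] | None = None,
           n_inventoried_species: int | None = None,
           n_preselected_biopumps: int | None = None,
           target_area_mha: float | None = None,
           marginal_area_mha: float | None = None,
           net_positive_area_mha: float | None = None) -> dict:
    """Derived summary statistics over the whole exercise.

    Integer percentages are rounded half-up; annual rates to two decimals.
    Every share also reports its numerator and denominator.
    """
    viable = [m for m in matches if m.matched]
    net_pos = [r for r in results if r.net_positive]
    out: dict = {
        "theoretical_matches": count_theoretical(n_areas, n_species),
        "viable_matches": len(viable),
        "net_positive_pairs": len(net_pos),
        "best_cases": int(len(best)),
        "areas_with_no_positive_pair":
            len({(r.region_id, r.gez_id) for r in results})
            - len({(r.region_id, r.gez_id) for r in net_pos}),
    }
    if viable:
        out["pct_viable_of_theoretical"] = share_pct(len(viable), out["theoretical_matches"])
        out["pct_net_positive_of_viable"] = share_pct(len(net_pos), len(viable))
    matched_taxa = {m.taxon for m in viable}
    out["matched_species"] = len(matched_taxa)
    if species_by_taxon is not None:
        out["matched_biopumps"] = len({species_by_taxon[t].name for t in matched_taxa})
    if n_inventoried_species:
        out["pct_species_suitable"] = share_pct(len(matched_taxa), n_inventoried_species)
    if n_preselected_biopumps and "matched_biopumps" in out:
        out["pct_biopumps_matched"] = share_pct(out["matched_biopumps"], n_preselected_biopumps)
    if len(best):
        out["net_soc_min"] = round(float(best["net_soc"].min()), 2)
        out["net_soc_max"] = round(float(best["net_soc"].max()), 2)
        out["annualized_min"] = round(float(best["annualized_net"].min()), 2)
        out["annualized_max"] = round(float(best["annualized_net"].max()), 2)
        out["best_case_biopumps"] = len(set(best["taxon"]))
        test = None
        if len(best) >= 2:
            test = paired_t_test(best["soc_init"], best["soc_final"])
            out["paired_t"] = test.t
            out["paired_p"] = test.p
            out["paired_degenerate"] = test.degenerate
    if target_area_mha and marginal_area_mha:
        out["pct_target_of_marginal"] = share_pct(target_area_mha, marginal_area_mha)
    if net_positive_area_mha is not None and target_area_mha:
        out["pct_net_positive_area_of_target"] = share_pct(net_positive_area_mha, target_area_mha)
    return out
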