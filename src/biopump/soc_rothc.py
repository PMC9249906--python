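"""Five-pool monthly soil-organic-carbon turnover (RothC v26.3 semantics).

The soil carbon stock is split into decomposable plant material (DPM),
resistant plant material (RPM), microbial biomass (BIO), humified organic
matter (HUM) and an inert pool (IOM). Each active pool decays monthly as

    pool × (1 − exp(−a·b·c·k/12))

where ``k`` is the pool's annual rate constant and ``a``, ``b``, ``c`` are
the temperature, moisture and soil-cover rate modifiers. Decomposed carbon
splits between respired CO₂, BIO and HUM according to the clay-dependent
partitioning ratio; incoming plant carbon splits between DPM and RPM by a
land-use-specific ratio (1.44 for cropland/grassland vegetation, 0.25 for
woodland). The moisture modifier is driven by an accumulated topsoil
moisture deficit (TSMD) bookkeeping of monthly precipitation minus
evapotranspiration.

Pool initialization from a measured total stock uses pedotransfer
regressions on SOC and clay for RPM, HUM and BIO, the Falloon regression
``IOM = 0.049·SOC^1.139`` for the inert pool, and assigns the remainder to
DPM (floored at zero with proportional renormalization so the pools sum to
the measured stock exactly).

All numeric constants are the published RothC v26.3 parametrization and are
carried in :class:`RothCParams` so alternative calibrations can be swapped
in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RothCParams",
    "RothCState",
    "temperature_modifier",
    "max_tsmd",
    "moisture_modifier",
    "partition_fractions",
    "init_pools",
    "step_month",
    "run_rothc",
]

POOLS = ("dpm", "rpm", "bio", "hum", "iom")

#: DPM/RPM ratio of incoming plant material by vegetation class
DPM_RPM_BY_LIFE_FORM = {"crop": 1.44, "grass": 1.44, "tree": 0.25}


@dataclass(frozen=True)
class RothCParams:
    """Rate constants and modifier constants (RothC v26.3 defaults)."""

    k_dpm: float = 10.0       # yr⁻¹
    k_rpm: float = 0.3
    k_bio: float = 0.66
    k_hum: float = 0.02
    bio_split: float = 0.46   # BIO share of the non-CO₂ decomposition products
    hum_split: float = 0.54
    cover_rate_modifier: float = 0.6   # c when soil is vegetated
    tsmd_bare_divisor: float = 1.8
    b_min: float = 0.2
    tsmd_threshold: float = 0.444      # |acc|/|max| below which b = 1
    # temperature response
    t_a: float = 47.91
    t_b: float = 106.06
    t_c: float = 18.27
    # CO₂/(BIO+HUM) clay response
    x_a: float = 1.67
    x_b: float = 1.85
    x_c: float = 1.60
    x_d: float = 0.0786
    # pedotransfer pool-initialization regressions (on SOC and clay)
    iom_a: float = 0.049
    iom_b: float = 1.139
    rpm_coef: tuple = (0.1847, 0.1555, 1.2750, -0.1158)
    hum_coef: tuple = (0.7148, 0.5069, 0.3421, 0.0184)
    bio_coef: tuple = (0.0140, 0.0075, 8.8473, 0.0567)

    def __post_init__(self) -> None:
        if not math.isclose(self.bio_split + self.hum_split, 1.0):
            raise ValueError("BIO/HUM split must sum to 1")
        for name in ("k_dpm", "k_rpm", "k_bio", "k_hum"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k(self) -> dict[str, float]:
        return {"dpm": self.k_dpm, "rpm": self.k_rpm, "bio": self.k_bio, "hum": self.k_hum}


DEFAULT_PARAMS = RothCParams()


@dataclass
class RothCState:
    """Five carbon pools (Mg C ha⁻¹) plus the accumulated TSMD (mm, ≤ 0)."""

    dpm: float
    rpm: float
    bio: float
    hum: float
    iom: float
    acc_tsmd: float = 0.0

    def __post_init__(self) -> None:
        for p in POOLS:
            if getattr(self, p) < 0:
                raise ValueError(f"pool {p} is negative")
        if self.acc_tsmd > 0:
            raise ValueError("accumulated TSMD must be ≤ 0")

    @property
    def total(self) -> float:
        return self.dpm + self.rpm + self.bio + self.hum + self.iom


def temperature_modifier(t_mean: float, params: RothCParams = DEFAULT_PARAMS) -> float:
    """Temperature rate modifier ``a``; zero at and below −18.27 °C."""
    if t_mean <= -params.t_c:
        return 0.0
    return params.t_a / (1.0 + math.exp(params.t_b / (t_mean + params.t_c)))


def max_tsmd(clay_pct: float, depth_cm: float, covered: bool,
             params: RothCParams = DEFAULT_PARAMS) -> float:
    """Maximum topsoil moisture deficit (mm, negative).

    Quadratic in clay for a 23-cm reference layer, scaled to the actual
    topsoil depth; bare soil can only dry to 1/1.8 of the vegetated deficit.
    """
    if not 0 <= clay_pct <= 100:
        raise ValueError("clay percentage outside [0, 100]")
    if depth_cm <= 0:
        raise ValueError("soil depth must be positive")
    m = -(20.0 + 1.3 * clay_pct - 0.01 * clay_pct ** 2) * depth_cm / 23.0
    return m if covered else m / params.tsmd_bare_divisor


def moisture_modifier(p: float, pet: float, acc_tsmd: float, max_tsmd_mm: float,
                      params: RothCParams = DEFAULT_PARAMS) -> tuple[float, float]:
    """Moisture rate modifier ``b`` and the updated accumulated deficit.

    The deficit accumulates by (P − PET) each month, clamped to
    [maxTSMD, 0]; ``b`` is 1 while the deficit is shallower than 0.444 of
    the maximum and declines linearly to 0.2 at the maximum deficit.
    """
    if p < 0 or pet < 0:
        raise ValueError("precipitation and evapotranspiration must be ≥ 0")
    acc = min(0.0, max(max_tsmd_mm, acc_tsmd + (p - pet)))
    amax = abs(max_tsmd_mm)
    if amax == 0 or abs(acc) < params.tsmd_threshold * amax or \
            math.isclose(abs(acc), params.tsmd_threshold * amax):
        b = 1.0
    else:
        b = params.b_min + (1.0 - params.b_min) * (amax - abs(acc)) / ((1.0 - params.tsmd_threshold) * amax)
    return b, acc


def partition_fractions(clay_pct: float,
                        params: RothCParams = DEFAULT_PARAMS) -> tuple[float, float, float]:
    """Split of decomposed carbon into (CO₂, BIO, HUM); sums to 1."""
    if not 0 <= clay_pct <= 100:
        raise ValueError("clay percentage outside [0, 100]")
    x = params.x_a * (params.x_b + params.x_c * math.exp(-params.x_d * clay_pct))
    return x / (x + 1.0), params.bio_split / (x + 1.0), params.hum_split / (x + 1.0)


def init_pools(soc0: float, clay_pct: float,
               params: RothCParams = DEFAULT_PARAMS) -> RothCState:
    """Pedotransfer initialization of the five pools from a measured stock.

    IOM follows the Falloon regression; RPM, HUM and BIO follow regressions
    on SOC and clay; DPM takes the remainder. If the regressions overshoot
    the stock, DPM is floored at zero and RPM/HUM/BIO are rescaled
    proportionally so the pools sum to ``soc0`` exactly.
    """
    if soc0 <= 0:
        raise ValueError("initial SOC must be positive")
    iom = min(params.iom_a * soc0 ** params.iom_b, soc0)

    def reg(coef):
        a, b, c, d = coef
        return (a * soc0 + b) * (clay_pct + c) ** d

    rpm, hum, bio = reg(params.rpm_coef), reg(params.hum_coef), reg(params.bio_coef)
    rest = soc0 - iom
    active = rpm + hum + bio
    dpm = rest - active
    if dpm < 0:
        scale = rest / active if active > 0 else 0.0
        rpm, hum, bio = rpm * scale, hum * scale, bio * scale
        dpm = 0.0
    return RothCState(dpm=dpm, rpm=rpm, bio=bio, hum=hum, iom=iom)


def step_month(state: RothCState, a: float, b: float, c: float, c_input: float,
               dpm_rpm_ratio: float, clay_pct: float,
               params: RothCParams = DEFAULT_PARAMS) -> tuple[RothCState, float]:
    """Advance the pools one month; returns the new state and respired CO₂.

    Existing pools decay by exp(−a·b·c·k/12); the decomposed carbon splits
    into CO₂, BIO and HUM by the clay partition; this month's plant input
    then splits into DPM and RPM by ``ratio/(1+ratio) : 1/(1+ratio)``. Mass
    balance Δtotal = input − CO₂ holds exactly.
    """
    if min(a, b, c) < 0 or c_input < 0:
        raise ValueError("modifiers and input must be non-negative")
    abc = a * b * c
    f_co2, f_bio, f_hum = partition_fractions(clay_pct, params)
    decayed = {}
    loss = 0.0
    for pool in ("dpm", "rpm", "bio", "hum"):
        v = getattr(state, pool)
        kept = v * math.exp(-abc * params.k[pool] / 12.0)
        decayed[pool] = kept
        loss += v - kept
    co2 = loss * f_co2
    dpm_share = dpm_rpm_ratio / (1.0 + dpm_rpm_ratio)
    new = RothCState(
        dpm=decayed["dpm"] + c_input * dpm_share,
        rpm=decayed["rpm"] + c_input * (1.0 - dpm_share),
        bio=decayed["bio"] + loss * f_bio,
        hum=decayed["hum"] + loss * f_hum,
        iom=state.iom,
        acc_tsmd=state.acc_tsmd,
    )
    return new, co2


def run_rothc(
    state0: RothCState,
    temp: np.ndarray,
    prec: np.ndarray,
    pet: np.ndarray,
    monthly_input,
    covered,
    years: int,
    clay_pct: float,
    depth_cm: float,
    dpm_rpm_ratio: float,
    params: RothCParams = DEFAULT_PARAMS,
    pan_correction: bool = False,
) -> pd.DataFrame:
    """Run the turnover model over recycled 12-month climate normals.

    ``monthly_input`` is a 12-vector of plant C additions (Mg C ha⁻¹ per
    month); ``covered`` a 12-vector of booleans (vegetated soil → cover
    rate modifier 0.6 and full TSMD depth). ``pan_correction`` multiplies
    evapotranspiration by 0.75 when the supplied series is open-pan rather
    than potential evapotranspiration.

    Returns a trajectory with one row per month (pools, total, CO₂) plus a
    leading row for the initial state.
    """
    if years < 1:
        raise ValueError("simulation needs at least one year")
    temp, prec, pet = (np.asarray(v, dtype=float) for v in (temp, prec, pet))
    monthly_input = np.asarray(monthly_input, dtype=float)
    covered = np.asarray(covered, dtype=bool)
    for name, v in (("temp", temp), ("prec", prec), ("pet", pet),
                    ("monthly_input", monthly_input), ("covered", covered)):
        if v.shape != (12,):
            raise ValueError(f"{name} must be a 12-month vector")
    pet_eff = pet * (0.75 if pan_correction else 1.0)

    state = state0
    rows = [{"month": 0, **{p: getattr(state, p) for p in POOLS},
             "total": state.total, "co2": 0.0}]
    for step in range(12 * years):
        m = step % 12
        a = temperature_modifier(temp[m], params)
        mt = max_tsmd(clay_pct, depth_cm, bool(covered[m]), params)
        b, acc = moisture_modifier(prec[m], pet_eff[m], state.acc_tsmd, mt, params)
        c = params.cover_rate_modifier if covered[m] else 1.0
        state = replace(state, acc_tsmd=acc)
        state, co2 = step_month(state, a, b, c, monthly_input[m],
                                dpm_rpm_ratio, clay_pct, params)
        rows.append({"month": step + 1, **{p: getattr(state, p) for p in POOLS},
                     "total": state.total, "co2": co2})
    return pd.DataFrame(rows)
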