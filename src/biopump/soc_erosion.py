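"""Annual SOC loss to water erosion, coupled offline to the SOC trajectory.

The mapped soil-loss rate (RUSLE-based, Mg soil ha⁻¹ yr⁻¹) is rescaled to
the candidate vegetation by the ratio of cover-management factors — RUSLE
is linear in the C factor — and converted to a carbon flux by multiplying
with the SOC concentration of the topsoil (simulated stock over fixed
topsoil mass). By default the losses are bookkept outside the turnover
model ("offline"): the reported net stock is final SOC minus cumulative
eroded SOC, and erosion never feeds back into the pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ErosionResult", "adjust_soil_loss", "soc_erosion_annual", "cumulative_erosion"]

#: default reference cover factor of the soil-loss map on bare/sparse land
C_REF_DEFAULT = 0.5


@dataclass(frozen=True)
class ErosionResult:
    """Yearly SOC erosion series and its cumulative sum (Mg C ha⁻¹)."""

    annual_soc_loss: pd.Series
    cumulative: float

    def __post_init__(self) -> None:
        if (self.annual_soc_loss < 0).any():
            raise ValueError("erosion losses cannot be negative")


def adjust_soil_loss(e_map: float, c_new: float, c_ref: float = C_REF_DEFAULT) -> float:
    """Rescale a mapped soil-loss rate to a new cover-management factor.

    RUSLE predictions are proportional to the C factor, so
    ``e_adj = e_map × c_new / c_ref``. ``c_new = 0`` (perfect cover) is the
    zero-erosion boundary; ``c_ref`` must be positive.
    """
    if e_map < 0:
        raise ValueError("soil loss must be non-negative")
    if not 0 <= c_new <= 1:
        raise ValueError("cover factor outside [0, 1]")
    if not 0 < c_ref <= 1:
        raise ValueError("reference cover factor must be in (0, 1]")
    return e_map * c_new / c_ref


def topsoil_mass(bulk_density: float, depth_cm: float) -> float:
    """Topsoil mass per hectare, Mg ha⁻¹ (BD in Mg m⁻³, depth in cm)."""
    m = bulk_density * depth_cm * 100.0
    if m <= 0:
        raise ValueError("topsoil mass must be positive")
    return m


def soc_erosion_annual(e_adj: float, soc_stock: float, bulk_density: float,
                       depth_cm: float, enrichment: float = 1.0) -> float:
    """Carbon eroded in one year, Mg C ha⁻¹ yr⁻¹.

    The eroded soil carries the topsoil's carbon concentration
    (stock / topsoil mass), optionally scaled by an enrichment ratio for
    the preferential loss of carbon-rich fines.
    """
    if min(e_adj, soc_stock, enrichment) < 0:
        raise ValueError("inputs must be non-negative")
    return e_adj * enrichment * soc_stock / topsoil_mass(bulk_density, depth_cm)


def cumulative_erosion(soc_trajectory, e_adj: float, bulk_density: float,
                       depth_cm: float, years: int,
                       enrichment: float = 1.0) -> ErosionResult:
    """Erode against a yearly SOC trajectory without feeding back.

    ``soc_trajectory`` holds the simulated total stock at each year
    (length ≥ ``years``); the year-y loss uses the year-y stock. The
    cumulative total is the plain sum of the annual series.
    """
    traj = np.asarray(soc_trajectory, dtype=float)
    if len(traj) < years:
        raise ValueError("trajectory shorter than the requested horizon")
    losses = [
        soc_erosion_annual(e_adj, traj[y], bulk_density, depth_cm, enrichment)
        for y in range(years)
    ]
    series = pd.Series(losses, index=pd.RangeIndex(1, years + 1, name="year"))
    return ErosionResult(annual_soc_loss=series, cumulative=float(series.sum()))
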