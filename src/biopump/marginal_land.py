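"""Identification of SOC-deficient marginal land.

Five filtering sub-steps produce the marginal-land mask:

1. candidate land covers — bare and sparsely vegetated (<15% vegetation);
2. cropland abandonment — cells that were cropland in an earlier land-cover
   epoch and transitioned to a semi-natural cover in the later epoch;
3. SOC deficiency — topsoil stock in (0, 50] Mg C ha⁻¹, binned in 10-Mg
   classes;
4. exclusion of protected areas;
5. exclusion of problem land with (sub-)severe soil/terrain restrictions.

Steps 3–5 are pure intersections and therefore order-independent. Every
retained cell carries exactly one provenance code; a cell that is both a
candidate cover and an abandonment transition is counted as abandoned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geodata import RasterLayer

__all__ = [
    "PROVENANCE_BARE",
    "PROVENANCE_SPARSE",
    "PROVENANCE_ABANDONED",
    "LandCoverLegend",
    "MarginalLandMask",
    "select_candidate_cover",
    "detect_abandonment",
    "filter_soc",
    "exclude_protected",
    "exclude_problem_land",
    "identify_marginal_land",
]

# provenance codes, in increasing precedence
PROVENANCE_BARE = 1
PROVENANCE_SPARSE = 2
PROVENANCE_ABANDONED = 3

PROVENANCE_NAMES = {
    PROVENANCE_BARE: "bare",
    PROVENANCE_SPARSE: "sparse",
    PROVENANCE_ABANDONED: "abandoned",
}

ROLES = frozenset(
    {"cropland", "mosaic_cropland", "grassland", "sparse", "bare",
     "shrubland", "herbaceous_mosaic", "other"}
)

#: land-cover roles that qualify as candidate marginal covers
CANDIDATE_ROLES = frozenset({"bare", "sparse"})

#: destination roles that mark a cropland→semi-natural abandonment transition
ABANDONMENT_TARGETS = frozenset(
    {"mosaic_cropland", "grassland", "sparse", "bare", "herbaceous_mosaic", "shrubland"}
)

SOC_THRESHOLD_DEFAULT = 50.0  # Mg C ha⁻¹ to 30 cm
SOC_BIN_WIDTH = 10.0


class LegendError(ValueError):
    """An unmapped land-cover or problem-land code was encountered."""


@dataclass(frozen=True)
class LandCoverLegend:
    """Mapping from integer land-cover class codes to functional roles."""

    roles: dict[int, str]

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise LegendError(f"unknown land-cover roles: {sorted(bad)}")

    @classmethod
    def from_csv(cls, path=None) -> "LandCoverLegend":
        """Load a ``code,role[,label]`` CSV; defaults to the packaged
        ESA-CCI-style 22-class legend."""
        if path is None:
            with resources.files("biopump").joinpath("data/land_cover_legend.csv").open() as fh:
                df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
        if df["code"].duplicated().any():
            raise LegendError("legend maps a code more than once")
        return cls(dict(zip(df["code"].astype(int), df["role"].astype(str))))

    def role_grid(self, lc: RasterLayer) -> np.ndarray:
        """Per-cell role strings; raises on any unmapped valid code."""
        codes = np.asarray(lc.values)
        valid = lc.valid_mask()
        present = set(np.unique(codes[valid]).astype(int).tolist())
        unmapped = present - set(self.roles)
        if unmapped:
            raise LegendError(f"land-cover codes not in legend: {sorted(unmapped)}")
        out = np.full(codes.shape, "other", dtype=object)
        for code, role in self.roles.items():
            out[codes == code] = role
        out[~valid] = "nodata"
        return out


def load_severity_codes(path=None) -> frozenset[int]:
    """Problem-land codes counted as (sub-)severe; defaults to the packaged
    table covering the classic agricultural problem-land typologies (too
    cold, too dry, steep slopes, shallow, poorly drained, saline/sodic,
    acid sulphate, peats)."""
    if path is None:
        with resources.files("biopump").joinpath("data/problem_severity.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return frozenset(df.loc[df["severe"] == 1, "code"].astype(int))


@dataclass
class MarginalLandMask:
    """Boolean marginal-land mask with per-cell provenance and SOC class."""

    mask: np.ndarray          # bool grid
    provenance: np.ndarray    # int grid, 0 where mask is False
    soc_class: np.ndarray     # int grid in 1..5 where mask True, else 0
    dropped_negative_soc: int = 0
    report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if ((self.provenance > 0) != self.mask).any():
            raise ValueError("provenance must be defined exactly on masked cells")
        if ((self.soc_class > 0) != self.mask).any():
            raise ValueError("soc_class must be defined exactly on masked cells")


def _require_same_grid(a: RasterLayer, b: RasterLayer) -> None:
    if not a.same_grid(b):
        raise ValueError("layers must be aligned to the same grid first")


def select_candidate_cover(lc: RasterLayer, legend: LandCoverLegend):
    """Step 1: retain bare and sparsely vegetated covers.

    Returns ``(mask, provenance)`` with provenance codes
    :data:`PROVENANCE_BARE` / :data:`PROVENANCE_SPARSE`.
    """
    if lc.kind != "categorical":
        raise ValueError("land cover must be a categorical raster")
    roles = legend.role_grid(lc)
    mask = np.isin(roles, list(CANDIDATE_ROLES))
    prov = np.zeros(lc.shape, dtype=np.int8)
    prov[roles == "bare"] = PROVENANCE_BARE
    prov[roles == "sparse"] = PROVENANCE_SPARSE
    return mask, prov


def detect_abandonment(
    lc_t0: RasterLayer, lc_t1: RasterLayer, legend: LandCoverLegend
) -> np.ndarray:
    """Step 2: cropland in the earlier epoch that became a semi-natural cover.

    A transition counts when the earlier role is ``cropland`` and the later
    role is one of mosaic cropland/natural vegetation, grassland, sparse
    vegetation, bare, mosaic herbaceous cover or shrubland.
    """
    _require_same_grid(lc_t0, lc_t1)
    r0 = legend.role_grid(lc_t0)
    r1 = legend.role_grid(lc_t1)
    return (r0 == "cropland") & np.isin(r1, list(ABANDONMENT_TARGETS))


def filter_soc(
    mask: np.ndarray, soc: RasterLayer, threshold: float = SOC_THRESHOLD_DEFAULT
):
    """Step 3: keep cells with topsoil SOC in (0, threshold] and bin them.

    Class = ceil(SOC / 10) over bins (0,10] … (40,50]; the upper bound is
    inclusive. Zero-SOC cells are treated as no-soil and excluded. Negative
    SOC values are reported and dropped.

    Returns ``(mask, soc_class, n_negative_dropped)``.
    """
    if soc.kind != "continuous":
        raise ValueError("SOC must be a continuous raster")
    v = np.asarray(soc.values, dtype=float)
    valid = soc.valid_mask()
    negative = mask & valid & (v < 0)
    keep = mask & valid & (v > 0) & (v <= threshold) & ~negative
    soc_class = np.zeros(v.shape, dtype=np.int8)
    soc_class[keep] = np.ceil(v[keep] / SOC_BIN_WIDTH).astype(np.int8)
    return keep, soc_class, int(negative.sum())


def exclude_protected(mask: np.ndarray, protected: RasterLayer) -> np.ndarray:
    """Step 4: remove cells falling inside protected areas (nonzero code)."""
    if mask.shape != protected.shape:
        raise ValueError("protected-area raster must be on the mask grid")
    p = protected.valid_mask() & (np.asarray(protected.values) != 0)
    return mask & ~p


def exclude_problem_land(
    mask: np.ndarray, problem: RasterLayer, severity_codes
) -> np.ndarray:
    """Step 5: remove cells whose problem-land code is (sub-)severe."""
    if mask.shape != problem.shape:
        raise ValueError("problem-land raster must be on the mask grid")
    bad = problem.valid_mask() & np.isin(np.asarray(problem.values), list(severity_codes))
    return mask & ~bad


def identify_marginal_land(
    lc_t0: RasterLayer,
    lc_t1: RasterLayer,
    soc: RasterLayer,
    protected: RasterLayer,
    problem: RasterLayer,
    legend: LandCoverLegend,
    severity_codes,
    soc_threshold: float = SOC_THRESHOLD_DEFAULT,
    cell_areas: np.ndarray | None = None,
) -> MarginalLandMask:
    """Run all five sub-steps and report composition by provenance.

    The final mask is ``(candidates ∪ abandoned) ∩ SOC-deficient ∩
    ¬protected ∩ ¬problem``. Abandonment takes provenance precedence over
    sparse, which takes precedence over bare. The composition report gives
    the share of retained area per provenance (percentages sum to 100 when
    anything is retained).
    """
    cand_mask, prov = select_candidate_cover(lc_t1, legend)
    abandoned = detect_abandonment(lc_t0, lc_t1, legend)
    union = cand_mask | abandoned
    provenance = prov.copy()
    provenance[abandoned] = PROVENANCE_ABANDONED

    kept, soc_class, n_neg = filter_soc(union, soc, soc_threshold)
    kept = exclude_protected(kept, protected)
    kept = exclude_problem_land(kept, problem, severity_codes)

    provenance = np.where(kept, provenance, 0).astype(np.int8)
    soc_class = np.where(kept, soc_class, 0).astype(np.int8)

    areas = np.ones(kept.shape) if cell_areas is None else np.asarray(cell_areas)
    rows = []
    total = float(areas[kept].sum())
    for code, name in PROVENANCE_NAMES.items():
        sel = kept & (provenance == code)
        a = float(areas[sel].sum())
        rows.append({
            "provenance": name,
            "cells": int(sel.sum()),
            "area": a,
            "share_pct": 100.0 * a / total if total > 0 else np.nan,
        })
    report = pd.DataFrame(rows)
    return MarginalLandMask(
        mask=kept, provenance=provenance, soc_class=soc_class,
        dropped_negative_soc=n_neg, report=report,
    )
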