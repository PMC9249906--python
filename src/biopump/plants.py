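"""Species trait records, climate-zone harmonization and carbon inputs.

Each candidate species carries pedoclimatic tolerance ranges (temperature,
precipitation, pH, texture, altitude, climate zones), life-form and
lifecycle descriptors, dry-matter fractions with carbon contents, and a
RUSLE cover-management factor.

The annual organic-carbon input to the soil follows a fractioning and
partitioning scheme over four compartments — product, stem, leaf
(aboveground) and root (belowground). For each fraction f the contribution
is ``dm_f × c_f × return_f`` where dm is dry matter (Mg DM ha⁻¹), c the
carbon content (fraction) and return the share left in the field. Annual
species return everything within the year. Perennials are annualized over
the rotation lifetime assuming an uneven-aged stand: stem, product and
evergreen-leaf returns are spread linearly over the lifetime, deciduous
leaves fall (and return) every year, and root carbon — which stays in the
soil for the whole rotation — is divided by the lifetime in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRecord",
    "CInputProfile",
    "load_species",
    "load_koppen_gez_mapping",
    "harmonize_climate_zones",
    "classify_life_form",
    "annual_c_input",
]

TEXTURES = ("coarse", "medium", "fine")
FRACTIONS = ("product", "stem", "leaf", "root")

#: accepted life-form descriptors → canonical class
_LIFE_FORM_RULES = {
    # herbaceous, graminoid and small woody/herbaceous shrubs behave as grassland
    "grass": "grass", "graminoid": "grass", "herb": "grass", "herbaceous": "grass",
    "bamboo": "grass", "banana_like": "grass", "small_shrub": "grass",
    "herbaceous_shrub": "grass",
    # cultivated annuals and row crops
    "crop": "crop", "annual_crop": "crop", "cereal": "crop", "vegetable": "crop",
    # trees and tree-like woody shrubs
    "tree": "tree", "woody": "tree", "woody_shrub": "tree", "coppice": "tree",
    "short_rotation_coppice": "tree", "orchard": "tree",
}


class SpeciesValidationError(ValueError):
    pass


@dataclass
class SpeciesRecord:
    """One plant species with tolerances and carbon-input parameters."""

    name: str
    taxon: str
    life_form: str              # grass | crop | tree
    lifecycle: str              # annual | perennial
    lifetime_yr: float
    temp_abs: tuple[float, float]       # °C, mean annual
    prec_abs: tuple[float, float]       # mm yr⁻¹
    ph_abs: tuple[float, float]
    texture_ok: frozenset[str]
    alt_abs: tuple[float, float]        # m
    gez_ok: frozenset[int]
    frac_dm: dict[str, float]           # Mg DM ha⁻¹ (per yr, or per rotation for perennials)
    c_content: dict[str, float]         # carbon fraction of DM, 0..1
    soil_return: dict[str, float]       # share left in field, 0..1 (root implicitly 1)
    deciduous: bool = False
    cover_factor: float = 0.2           # RUSLE C factor, (0, 1]
    cover_months: frozenset[int] = frozenset(range(1, 13))
    dpm_rpm_ratio: float | None = None  # override; default set by life form

    def __post_init__(self) -> None:
        errors = self.validation_errors()
        if errors:
            raise SpeciesValidationError("; ".join(errors))

    def validation_errors(self) -> list[str]:
        errs = []
        for rng_name in ("temp_abs", "prec_abs", "ph_abs", "alt_abs"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                errs.append(f"{rng_name}: min {lo} > max {hi}")
        if self.life_form not in ("grass", "crop", "tree"):
            errs.append(f"life_form: unknown {self.life_form!r}")
        if self.lifecycle not in ("annual", "perennial"):
            errs.append(f"lifecycle: unknown {self.lifecycle!r}")
        if self.lifetime_yr < 1:
            errs.append(f"lifetime_yr: {self.lifetime_yr} < 1")
        if not self.gez_ok:
            errs.append("gez_ok: empty climate-zone set")
        if not set(self.texture_ok) <= set(TEXTURES):
            errs.append(f"texture_ok: unknown textures {set(self.texture_ok) - set(TEXTURES)}")
        for frac, share in self.soil_return.items():
            if not 0 <= share <= 1:
                errs.append(f"soil_return[{frac}]: {share} outside [0, 1]")
        for frac, c in self.c_content.items():
            if not 0 <= c <= 1:
                errs.append(f"c_content[{frac}]: {c} outside [0, 1]")
        for frac, dm in self.frac_dm.items():
            if dm < 0:
                errs.append(f"frac_dm[{frac}]: negative")
        if not 0 < self.cover_factor <= 1:
            errs.append(f"cover_factor: {self.cover_factor} outside (0, 1]")
        return errs


@dataclass(frozen=True)
class CInputProfile:
    """Annual organic-carbon input to the soil, Mg C ha⁻¹ yr⁻¹."""

    aboveground: float
    root: float

    @property
    def annual_c(self) -> float:
        return self.aboveground + self.root


def _parse_set(cell, cast=str):
    if pd.isna(cell) or str(cell).strip() == "":
        return frozenset()
    return frozenset(cast(tok.strip()) for tok in str(cell).split("|") if tok.strip())


_SCHEMA = [
    "name", "taxon", "life_form", "lifecycle", "lifetime_yr",
    "temp_min", "temp_max", "prec_min", "prec_max", "ph_min", "ph_max",
    "texture_ok", "alt_min", "alt_max", "gez_ok",
    "dm_product", "dm_stem", "dm_leaf", "dm_root",
    "c_product", "c_stem", "c_leaf", "c_root",
    "ret_product", "ret_stem", "ret_leaf",
    "deciduous", "cover_factor", "cover_months",
]


def load_species(table, *, strict: bool = False):
    """Load a species trait CSV (or DataFrame).

    Returns ``(records, rejected)`` where ``rejected`` is a list of
    ``(row_index, taxon, message)`` diagnostics for rows violating the
    record invariants. With ``strict=True`` any rejection raises.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    missing_cols = [c for c in _SCHEMA if c not in df.columns]
    if missing_cols:
        raise SpeciesValidationError(f"trait table missing columns: {missing_cols}")
    if df.empty:
        raise SpeciesValidationError("trait table is empty")
    records: list[SpeciesRecord] = []
    rejected: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        try:
            rec = SpeciesRecord(
                name=str(row["name"]), taxon=str(row["taxon"]),
                life_form=str(row["life_form"]), lifecycle=str(row["lifecycle"]),
                lifetime_yr=float(row["lifetime_yr"]),
                temp_abs=(float(row["temp_min"]), float(row["temp_max"])),
                prec_abs=(float(row["prec_min"]), float(row["prec_max"])),
                ph_abs=(float(row["ph_min"]), float(row["ph_max"])),
                texture_ok=_parse_set(row["texture_ok"]),
                alt_abs=(float(row["alt_min"]) if not pd.isna(row["alt_min"]) else -500.0,
                         float(row["alt_max"])),
                gez_ok=_parse_set(row["gez_ok"], int),
                frac_dm={f: float(row[f"dm_{f}"]) for f in FRACTIONS},
                c_content={f: float(row[f"c_{f}"]) for f in FRACTIONS},
                soil_return={f: float(row[f"ret_{f}"]) for f in ("product", "stem", "leaf")},
                deciduous=bool(row["deciduous"]),
                cover_factor=float(row["cover_factor"]),
                cover_months=_parse_set(row["cover_months"], int) or frozenset(range(1, 13)),
                dpm_rpm_ratio=float(row["dpm_rpm_ratio"])
                if "dpm_rpm_ratio" in df.columns and not pd.isna(row.get("dpm_rpm_ratio"))
                else None,
            )
        except (SpeciesValidationError, ValueError) as exc:
            rejected.append((int(idx), str(row.get("taxon", "?")), str(exc)))
            continue
        records.append(rec)
    if strict and rejected:
        msgs = "; ".join(f"row {i} ({t}): {m}" for i, t, m in rejected)
        raise SpeciesValidationError(msgs)
    return records, rejected


def load_koppen_gez_mapping(path=None) -> dict[str, frozenset[int]]:
    """Load the Köppen→GEZ harmonization table (editable CSV; a packaged
    default ships with the library)."""
    if path is None:
        with resources.files("biopump").joinpath("data/koppen_gez.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    out: dict[str, set[int]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["koppen"]), set()).add(int(row["gez_id"]))
    return {k: frozenset(v) for k, v in out.items()}


def harmonize_climate_zones(koppen_zones, mapping=None) -> frozenset[int]:
    """Union of the GEZ codes reachable from a set of Köppen codes.

    Raises ``KeyError`` listing every unmapped Köppen code.
    """
    if mapping is None:
        mapping = load_koppen_gez_mapping()
    unmapped = sorted(set(koppen_zones) - set(mapping))
    if unmapped:
        raise KeyError(f"Köppen codes without a GEZ mapping: {unmapped}")
    out: set[int] = set()
    for k in koppen_zones:
        out |= mapping[k]
    return frozenset(out)


def classify_life_form(descriptor: str) -> str:
    """Map a free-form life-form descriptor to grass / crop / tree.

    Small or herbaceous shrubs classify as grass; tree-like woody shrubs
    and short-rotation coppice classify as tree.
    """
    key = descriptor.strip().lower().replace(" ", "_").replace("-", "_")
    if key in _LIFE_FORM_RULES:
        return _LIFE_FORM_RULES[key]
    raise ValueError(f"unknown life-form descriptor: {descriptor!r}")


def annual_c_input(record: SpeciesRecord, root_multiplier: float = 1.0) -> CInputProfile:
    """Annual carbon input to the soil from one species.

    ``root_multiplier`` optionally folds rhizodeposition into the root
    compartment (default 1.0 = roots only).
    """
    if root_multiplier < 0:
        raise ValueError("root multiplier must be non-negative")
    life = record.lifetime_yr
    above = 0.0
    for frac in ("product", "stem", "leaf"):
        term = record.frac_dm[frac] * record.c_content[frac] * record.soil_return[frac]
        if record.lifecycle == "perennial":
            if frac == "leaf" and record.deciduous:
                pass  # deciduous leaves fall and return every year
            else:
                term /= life
        if term < 0:
            raise ValueError(f"negative carbon input from {frac}")
        above += term
    root_total = record.frac_dm["root"] * record.c_content["root"]
    root = root_multiplier * (root_total / life if record.lifecycle == "perennial" else root_total)
    return CInputProfile(aboveground=above, root=root)
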