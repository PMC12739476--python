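"""Derived leaf water, anatomy and stomatal indices.

All derived quantities are simple deterministic ratios of primary
measurements:

* relative water content  RWC = (FW - DW) / (TW - DW) * 100   [%]
* compactness ratio       CTR = PT / Lth * 100                [%]
* sponginess ratio        SR  = ST / Lth * 100                [%]
* stomatal aperture       SA  = pi/4 * SL * SW                [um^2]
* stomatal opening rate   SAR = open stomata / total stomata  [fraction]

SAR is kept as a fraction internally and only formatted as a percentage in
reports, which avoids double-scaling bugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .data_model import Direction, IndicatorTable
from .errors import DegenerateDataError

__all__ = [
    "WaterWeights",
    "LeafSection",
    "StomatalField",
    "relative_water_content",
    "compactness_ratio",
    "sponginess_ratio",
    "stomatal_aperture",
    "stomatal_opening_rate",
    "append_derived_indices",
    "DERIVED_INPUTS",
]


@dataclass(frozen=True)
class WaterWeights:
    """Fresh (FW), dry (DW) and turgid (TW) leaf mass in grams."""

    FW: float
    DW: float
    TW: float

    def __post_init__(self):
        if not (self.TW >= self.FW >= self.DW > 0):
            raise ValueError(
                f"leaf masses must satisfy TW >= FW >= DW > 0, got "
                f"FW={self.FW}, DW={self.DW}, TW={self.TW}"
            )


@dataclass(frozen=True)
class LeafSection:
    """Cross-section thicknesses in mm: whole leaf, epidermes, mesophyll layers."""

    Lth: float
    UET: float
    LET: float
    PT: float
    ST: float

    def __post_init__(self):
        vals = (self.Lth, self.UET, self.LET, self.PT, self.ST)
        if any(v <= 0 for v in vals):
            raise ValueError("all section thicknesses must be positive")
        if self.PT + self.ST > self.Lth * (1 + 1e-12):
            raise ValueError(
                f"palisade + spongy thickness ({self.PT + self.ST}) exceeds "
                f"leaf thickness ({self.Lth})"
            )


@dataclass(frozen=True)
class StomatalField:
    """One microscopy field: pore dimensions (um) and stomatal counts (per mm^2)."""

    SL: float
    SW: float
    SD_open: float
    SC: float

    def __post_init__(self):
        if self.SW < 0 or self.SL < self.SW:
            raise ValueError("need pore length SL >= pore width SW >= 0")
        if not (0 <= self.SD_open <= self.SC):
            raise ValueError("open-stomata count must lie in [0, total count]")


def relative_water_content(w: WaterWeights) -> float:
    """Leaf relative water content in percent of full turgor."""
    if w.TW == w.DW:
        raise DegenerateDataError("turgid mass equals dry mass: RWC undefined")
    return (w.FW - w.DW) / (w.TW - w.DW) * 100.0


def compactness_ratio(s: LeafSection) -> float:
    """Palisade tissue thickness as a percentage of leaf thickness."""
    return s.PT / s.Lth * 100.0


def sponginess_ratio(s: LeafSection) -> float:
    """Spongy tissue thickness as a percentage of leaf thickness."""
    return s.ST / s.Lth * 100.0


def stomatal_aperture(f: StomatalField) -> float:
    """Elliptical pore area pi/4 * length * width, in um^2."""
    return math.pi / 4.0 * f.SL * f.SW


def stomatal_opening_rate(f: StomatalField) -> float:
    """Fraction of stomata open in the field (0..1)."""
    if f.SC == 0:
        raise DegenerateDataError("total stomatal count is zero: SAR undefined")
    return f.SD_open / f.SC


#: derived code -> (required primary codes, computation)
DERIVED_INPUTS = {
    "RWC": (("FW", "DW", "TW"), lambda v: relative_water_content(WaterWeights(v["FW"], v["DW"], v["TW"]))),
    "CTR": (("PT", "Lth"), lambda v: v["PT"] / v["Lth"] * 100.0),
    "SR": (("ST", "Lth"), lambda v: v["ST"] / v["Lth"] * 100.0),
    "SA": (("SL", "SW"), lambda v: math.pi / 4.0 * v["SL"] * v["SW"]),
    "SAR": (("SOC", "SC"), lambda v: v["SOC"] / v["SC"]),
}

_DERIVED_META = {
    "RWC": ("Relative water content", Direction.HIGHER_IS_RESISTANT, "%"),
    "CTR": ("Compactness ratio", Direction.HIGHER_IS_RESISTANT, "%"),
    "SR": ("Sponginess ratio", Direction.NEUTRAL, "%"),
    "SA": ("Stomatal aperture", Direction.HIGHER_IS_RESISTANT, "um^2"),
    "SAR": ("Stomatal opening rate", Direction.HIGHER_IS_RESISTANT, "fraction"),
}


def append_derived_indices(
    table: IndicatorTable, which: list[str] | None = None
) -> IndicatorTable:
    """Append derived-index rows to a replicate-level table.

    For each ``(genotype, stage, replicate)`` that carries all primary codes a
    derived index needs (see :data:`DERIVED_INPUTS`), one new row with the
    derived code is appended.  Replicates lacking an input are skipped.
    Derived codes are registered with their direction tags if absent.
    """
    which = which or list(DERIVED_INPUTS)
    wide = table.df.pivot_table(
        index=["genotype", "stage", "replicate"], columns="indicator", values="value"
    )
    new_rows = []
    for code in which:
        needed, fn = DERIVED_INPUTS[code]
        if any(c not in wide.columns for c in needed):
            continue
        sub = wide.loc[:, list(needed)].dropna()
        for key, row in sub.iterrows():
            new_rows.append((*key, code, float(fn(row))))
        if code not in table.registry:
            name, direction, units = _DERIVED_META[code]
            table.registry.register_code(code, name, direction, units)
    if not new_rows:
        return table
    extra = pd.DataFrame(
        new_rows, columns=["genotype", "stage", "replicate", "indicator", "value"]
    )
    merged = pd.concat([table.df, extra], ignore_index=True)
    return IndicatorTable(merged, registry=table.registry, stages=table.stages)
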