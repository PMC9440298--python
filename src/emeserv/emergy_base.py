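"""Vegetation-fraction area correction and the renewable-emergy MAX rule."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .parameters import (
    RENEWABLE_NATURAL_FACTOR,
    RENEWABLE_ORDER,
    EcosystemClass,
    ParameterError,
    RenewableDrivers,
    UnitRecord,
)

__all__ = [
    "CorrectedArea",
    "MaxRenewableResult",
    "DegenerateSupportError",
    "vegetation_fraction",
    "correct_area",
    "max_renewable",
    "npp_service",
    "OPEN_WATER_CLASSES",
]

log = logging.getLogger(__name__)

#: open-water classes default to vf = 1 (no vegetation correction).
OPEN_WATER_CLASSES = frozenset(
    {EcosystemClass.LAKE, EcosystemClass.RESERVOIR_POND, EcosystemClass.RIVER}
)


class DegenerateSupportError(ValueError):
    """NDVI support has zero width (min == max)."""


@dataclass(frozen=True)
class CorrectedArea:
    vf: float
    corrected_area: float  # m²


@dataclass(frozen=True)
class MaxRenewableResult:
    value: float  # sej·yr⁻¹
    winner: str  # source label from RENEWABLE_ORDER
    natural_factor: str  # physical driver underlying the winner


def vegetation_fraction(ndvi: float, ndvi_min: float, ndvi_max: float) -> float:
    """Fractional vegetation cover from NDVI, clipped to [0, 1].

    (ndvi - ndvi_min) / (ndvi_max - ndvi_min); values outside the unit
    interval (anomalous NDVI beyond the support) are clipped with a logged
    warning so that the corrected area never exceeds the raw area.
    """
    if ndvi_max == ndvi_min:
        raise DegenerateSupportError(
            f"degenerate NDVI support: min == max == {ndvi_min}")
    if ndvi_max < ndvi_min:
        raise ParameterError("ndvi_max must exceed ndvi_min")
    vf = (ndvi - ndvi_min) / (ndvi_max - ndvi_min)
    if vf < 0.0 or vf > 1.0:
        log.warning("vegetation fraction %.4f outside [0,1]; clipping", vf)
        vf = min(1.0, max(0.0, vf))
    return vf


def correct_area(record: UnitRecord, vf: float | None = None, *,
                 water_vf_one: bool = True,
                 ndvi_min: float = -1.0, ndvi_max: float = 1.0) -> CorrectedArea:
    """Apply the vegetation-fraction correction to a record's raw area.

    Open-water classes (lake, reservoir/pond, river) use vf = 1 by default;
    pass ``water_vf_one=False`` to correct them like vegetated classes.
    An explicit ``vf`` overrides the NDVI-derived value.
    """
    if vf is None:
        if water_vf_one and record.ecosystem in OPEN_WATER_CLASSES:
            vf = 1.0
        else:
            vf = vegetation_fraction(record.ndvi, ndvi_min, ndvi_max)
    if not 0.0 <= vf <= 1.0:
        raise ParameterError(f"vf outside [0,1]: {vf}")
    return CorrectedArea(vf=vf, corrected_area=record.raw_area * vf)


def max_renewable(flows: RenewableDrivers) -> MaxRenewableResult:
    """Pick the maximum of the six renewable-emergy candidates.

    Ties break toward the earlier candidate in the fixed listing order
    (grouped solar/tidal/geothermal, wave, wind, rain chemical, runoff
    geopotential, runoff chemical).
    """
    cands = flows.candidates()
    winner = RENEWABLE_ORDER[0]
    best = cands[winner]
    for name in RENEWABLE_ORDER[1:]:
        if cands[name] > best:
            best = cands[name]
            winner = name
    return MaxRenewableResult(
        value=best, winner=winner,
        natural_factor=RENEWABLE_NATURAL_FACTOR[winner])


def npp_service(records: Iterable[UnitRecord]) -> tuple[list[MaxRenewableResult], float]:
    """Per-record MAX(R) values and their sum over the extent (sej·yr⁻¹)."""
    per_record = [max_renewable(r.renewable) for r in records]
    return per_record, float(sum(r.value for r in per_record))
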