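"""Double-counting-safe total ecosystem services per record and aggregate.

The five services that share the photosynthesis/renewable-input pathway
(NPP, CS, SB or SBa, GR, MR) enter totals through a MAX group — only the
largest of them is counted — while AP, SR/WP, CR (and the river-specific
HG) add on top.  River totals follow the four printed cases that prevent
hydropower and the renewable pathway being double counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .parameters import EcosystemClass, ParameterError
from .services import ServiceLedger

__all__ = [
    "TotalsRow",
    "MissingServiceError",
    "five_group_max",
    "total_terrestrial",
    "total_river",
    "total_other_aquatic",
    "total_record",
    "totals_table",
    "aggregate_totals",
    "change_rate",
]


class MissingServiceError(KeyError):
    """A service required by a totals formula is absent from the ledger."""


#: MAX-group listing order; ties break toward the earlier entry.
FIVE_GROUP_TERRESTRIAL = ("NPP", "CS", "SB", "GR", "MR")
FIVE_GROUP_AQUATIC = ("NPP", "CS", "SBa", "GR", "MR")


@dataclass(frozen=True)
class TotalsRow:
    unit_id: str
    ecosystem: EcosystemClass
    epoch: str
    total: float  # sej·yr⁻¹
    winner_service: str
    winner_value: float
    case_label: str  # "terrestrial", "aquatic", "river-a1/a2/a3/b"
    corrected_area: float
    tau: float


def _get(ledger: ServiceLedger, service: str) -> float:
    try:
        return ledger.services[service].value
    except KeyError:
        raise MissingServiceError(
            f"service {service} missing from ledger of "
            f"{ledger.unit_id}/{ledger.ecosystem.value}/{ledger.epoch}"
        ) from None


def five_group_max(ledger: ServiceLedger) -> tuple[str, float]:
    """Winner of the renewable-pathway MAX group (label, value).

    For aquatic classes the soil-building slot reads the sediment-building
    service; a eutrophic record has no SBa entry and the member is simply
    excluded from the group.
    """
    members = (FIVE_GROUP_TERRESTRIAL if ledger.ecosystem.is_terrestrial
               else FIVE_GROUP_AQUATIC)
    winner, best = None, -math.inf
    for name in members:
        if name in ("SB", "SBa") and name not in ledger.services:
            continue  # eutrophic exclusion
        v = _get(ledger, name)
        if v > best:
            winner, best = name, v
    assert winner is not None
    return winner, best


def total_terrestrial(ledger: ServiceLedger) -> TotalsRow:
    """max(NPP, CS, SB, GR, MR) + AP + SR + CR."""
    if not ledger.ecosystem.is_terrestrial:
        raise ParameterError("total_terrestrial requires a terrestrial class")
    winner, best = five_group_max(ledger)
    total = best + _get(ledger, "AP") + _get(ledger, "SR") + _get(ledger, "CR")
    return TotalsRow(ledger.unit_id, ledger.ecosystem, ledger.epoch, total,
                     winner, best, "terrestrial", ledger.corrected_area,
                     ledger.tau)


def total_other_aquatic(ledger: ServiceLedger) -> TotalsRow:
    """max(NPP, CS, SBa, GR, MR) + WP + AP + CR (wetland/lake/reservoir)."""
    eco = ledger.ecosystem
    if not (eco.is_aquatic and not eco.is_river):
        raise ParameterError("total_other_aquatic requires wetland/lake/reservoir")
    winner, best = five_group_max(ledger)
    total = best + _get(ledger, "WP") + _get(ledger, "AP") + _get(ledger, "CR")
    return TotalsRow(ledger.unit_id, eco, ledger.epoch, total, winner, best,
                     "aquatic", ledger.corrected_area, ledger.tau)


def total_river(ledger: ServiceLedger) -> TotalsRow:
    """River total under the hydropower-location cases.

    Case (a) applies when runoff geopotential energy won the renewable MAX
    rule; its sub-case depends on the dam position X.  Case (b) and a river
    without dams both use the plain additive form.  Materials transport is
    never part of the total.
    """
    if not ledger.ecosystem.is_river:
        raise ParameterError("total_river requires the river class")
    winner, best = five_group_max(ledger)
    wp, ap, cr = _get(ledger, "WP"), _get(ledger, "AP"), _get(ledger, "CR")
    hg = _get(ledger, "HG")
    x = ledger.dam_position
    case_a = ledger.max_renewable.winner == "runoff_geopotential"

    if x is None:
        # no dams: HG is zero, the plain additive form applies regardless
        total = best + wp + ap + hg + cr
        case = "river-b" if not case_a else "river-a-nodam"
    elif not case_a:
        total = best + wp + ap + hg + cr
        case = "river-b"
    elif x == 0.0:
        total = best + wp + ap + hg + cr
        case = "river-a1"
    elif x == 1.0:
        total = (1.0 - x) * best + wp + ap + hg + cr
        case = "river-a2"
    else:
        grp = max(best, hg)
        if hg > best:
            winner = "HG"
            best = hg
        total = grp + wp + ap + cr
        case = "river-a3"
    return TotalsRow(ledger.unit_id, ledger.ecosystem, ledger.epoch, total,
                     winner, best, case, ledger.corrected_area, ledger.tau)


def total_record(ledger: ServiceLedger) -> TotalsRow:
    eco = ledger.ecosystem
    if eco.is_terrestrial:
        return total_terrestrial(ledger)
    if eco.is_river:
        return total_river(ledger)
    return total_other_aquatic(ledger)


def totals_table(ledgers: Iterable[ServiceLedger]) -> pd.DataFrame:
    """Per-record totals as a tidy frame."""
    rows = [total_record(led) for led in ledgers]
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in rows],
            "ecosystem": [r.ecosystem.value for r in rows],
            "epoch": [r.epoch for r in rows],
            "total": [r.total for r in rows],
            "winner_service": [r.winner_service for r in rows],
            "winner_value": [r.winner_value for r in rows],
            "case_label": [r.case_label for r in rows],
            "corrected_area": [r.corrected_area for r in rows],
            "tau": [r.tau for r in rows],
        }
    )


Grouping = Literal["class", "unit", "region", "extent"]


def aggregate_totals(table: pd.DataFrame, grouping: Grouping = "extent",
                     region_spec=None) -> pd.DataFrame:
    """Sum per-record totals by class, unit, region or whole extent.

    All rows must belong to a single epoch; region grouping needs a
    :class:`~emeserv.parameters.RegionSpec`.
    """
    epochs = table["epoch"].unique()
    if len(epochs) > 1:
        raise ParameterError(f"mixed epochs in one aggregation: {sorted(epochs)}")
    if grouping == "class":
        keys = table["ecosystem"]
    elif grouping == "unit":
        keys = table["unit_id"]
    elif grouping == "region":
        if region_spec is None:
            raise ParameterError("region grouping requires a RegionSpec")
        keys = table["unit_id"].map(region_spec.zone_of)
    elif grouping == "extent":
        keys = pd.Series(["extent"] * len(table), index=table.index)
    else:
        raise ParameterError(f"unknown grouping {grouping!r}")
    out = table.groupby(keys)["total"].sum().rename_axis("group").reset_index()
    out["epoch"] = epochs[0] if len(epochs) else ""
    return out


def change_rate(totals_t0: pd.DataFrame, totals_t1: pd.DataFrame) -> pd.DataFrame:
    """(T₁ − T₀)/T₀ per group; undefined (NaN + flag) where T₀ = 0."""
    merged = totals_t0.merge(totals_t1, on="group", how="outer",
                             suffixes=("_t0", "_t1")).fillna({"total_t0": 0.0,
                                                              "total_t1": 0.0})
    t0 = merged["total_t0"]
    merged["rate"] = (merged["total_t1"] - t0).where(t0 != 0) / t0.where(t0 != 0)
    merged["undefined"] = t0 == 0
    return merged[["group", "total_t0", "total_t1", "rate", "undefined"]]
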