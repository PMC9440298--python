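"""First-order partial-differential attribution of ecosystem-service change.

The total of one ecosystem class is modelled as a bilinear function of
three drivers — the per-area natural intensity x of the winning MAX-group
service, the cognition driver τ, and the ecosystem area s:

    T(x, τ, s) = (1 + k2)·x·s + (k1 + k4)·s·τ + k3·s

Contributions are the baseline partial derivatives times the driver deltas;
everything of second order lands in the residual δ, which is reported, not
hidden.  Per-class contribution rates are then combined across ecosystems
by weighting with the class total-change, and summarized per precipitation
region in the printed-table layout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .parameters import ZONES, EcosystemClass, ParameterError, RegionSpec
from .services import ServiceLedger
from .totals import TotalsRow

__all__ = [
    "DriverModel",
    "Decomposition",
    "DecompositionConstants",
    "AttributionRecord",
    "AggregateAttribution",
    "decompose_general",
    "ecosystem_model",
    "fit_constants",
    "attribute_record",
    "attribute_pair",
    "contribution_rates",
    "aggregate_attribution",
    "regional_summary",
    "summary_from_contributions",
    "natural_factor_shares",
    "round_percent",
    "ratio_2dp",
    "DRIVERS",
]

log = logging.getLogger(__name__)

DRIVERS = ("R", "tau", "S")

#: natural factor carried by each possible MAX-group winner; NPP/SB defer
#: to the natural factor of the winning renewable flow.
_WINNER_FACTOR = {
    "MR": "evapotranspiration",
    "GR": "precipitation",
    "CS": "NPP",
    "HG": "elevation",
}


# ---------------------------------------------------------------------------
# generic first-order decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriverModel:
    """A named-driver model with an analytic value and partials."""

    drivers: tuple[str, ...]
    value: Callable[[Mapping[str, float]], float]
    partials: Mapping[str, Callable[[Mapping[str, float]], float]]


@dataclass
class Decomposition:
    """Result of a first-order decomposition of one model between states."""

    contributions: dict[str, float]
    delta: float  # residual: exact ΔY minus the first-order sum
    dY: float  # exact model change between the two states
    elasticities: dict[str, float | None]

    @property
    def total_check(self) -> float:
        return sum(self.contributions.values()) + self.delta


def decompose_general(model: DriverModel, state0: Mapping[str, float],
                      state1: Mapping[str, float]) -> Decomposition:
    """Cr_X = ∂Y/∂X|₀ · ΔX per driver; δ = ΔY_exact − ΣCr_X.

    Elasticities (∂Y/∂X · X/Y at baseline) are reported where defined and
    None otherwise; the contribution itself always uses the partial form,
    which is algebraically identical.
    """
    y0 = model.value(state0)
    y1 = model.value(state1)
    contributions: dict[str, float] = {}
    elasticities: dict[str, float | None] = {}
    for name in model.drivers:
        p = model.partials[name](state0)
        contributions[name] = p * (state1[name] - state0[name])
        elasticities[name] = p * state0[name] / y0 if y0 != 0 else None
    delta = (y1 - y0) - sum(contributions.values())
    return Decomposition(contributions, delta, y1 - y0, elasticities)


# ---------------------------------------------------------------------------
# the per-ecosystem bilinear model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecompositionConstants:
    """Absorbed constants of the per-class model and its case label."""

    k2: float  # quality-term factor on the winning service
    k14: float  # k1 + k4: health-term factor on s·τ
    k3: float  # linear-in-area remainder (soil retention, hydropower, …)
    case: str  # winning MAX-group service label ("NPP".."MR", "HG")

    def __post_init__(self) -> None:
        if self.k2 < 0 or self.k14 < 0:
            raise ParameterError("decomposition constants must be >= 0")


def ecosystem_model(constants: DecompositionConstants) -> DriverModel:
    """T = (1+k2)·x·s + k14·s·τ + k3·s with drivers (R, tau, S).

    Partials: ∂T/∂x = (1+k2)·s; ∂T/∂τ = k14·s;
    ∂T/∂s = (1+k2)·x + k14·τ + k3.
    """
    a = 1.0 + constants.k2
    b = constants.k14
    k3 = constants.k3

    def value(st: Mapping[str, float]) -> float:
        return a * st["R"] * st["S"] + b * st["S"] * st["tau"] + k3 * st["S"]

    partials = {
        "R": lambda st: a * st["S"],
        "tau": lambda st: b * st["S"],
        "S": lambda st: a * st["R"] + b * st["tau"] + k3,
    }
    return DriverModel(DRIVERS, value, partials)


def _hh_eq_parts(ledger: ServiceLedger) -> tuple[float, float]:
    """Summed human-health and ecosystem-quality sub-components."""
    hh = 0.0
    eq = 0.0
    for sv in ledger.services.values():
        hh += sv.components.get("HH", 0.0)
        eq += sv.components.get("EQ", 0.0)
    return hh, eq


def fit_constants(ledger0: ServiceLedger,
                  totals0: TotalsRow) -> DecompositionConstants:
    """Absorb the baseline ledger into the model constants.

    k2 scales the quality (PDF) terms against the winning service, k14 the
    health (DALY) terms against s·τ, and k3 picks up whatever part of the
    baseline total is linear in area but outside those two groups (soil
    retention, river hydropower), so the model reproduces the baseline
    total exactly.
    """
    s0 = totals0.corrected_area
    tau0 = totals0.tau
    win0 = totals0.winner_value
    hh, eq = _hh_eq_parts(ledger0)
    k2 = eq / win0 if win0 > 0 else 0.0
    k14 = hh / (s0 * tau0) if s0 * tau0 > 0 else 0.0
    rest = totals0.total - (1.0 + k2) * win0 - k14 * s0 * tau0
    k3 = rest / s0 if s0 > 0 else 0.0
    if k3 < 0 and not math.isclose(k3, 0.0, abs_tol=1e-30):
        # numerically possible when the winner's EQ accounting overshoots
        log.debug("clamping tiny negative k3 = %g", k3)
    return DecompositionConstants(k2=k2, k14=k14, k3=max(k3, 0.0),
                                  case=totals0.winner_service)


# ---------------------------------------------------------------------------
# per-(unit, class) attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributionRecord:
    """Attribution of one (unit, ecosystem class) change between epochs."""

    unit_id: str
    ecosystem: EcosystemClass
    contributions: dict[str, float]  # model contributions Cr_R/Cr_tau/Cr_S
    delta: float  # model residual
    dT_model: float
    dT_actual: float  # change in the accounted total
    rates: dict[str, float] | None  # per-driver rates incl. "delta"; None if undefined
    natural_factor: str
    winner_service: str
    elasticities: dict[str, float | None] = field(default_factory=dict)
    winner_switched: bool = False


def _natural_factor(ledger: ServiceLedger, winner: str) -> str:
    if winner in _WINNER_FACTOR:
        return _WINNER_FACTOR[winner]
    # NPP / SB / SBa inherit the factor of the winning renewable flow
    return ledger.max_renewable.natural_factor


def attribute_record(ledger0: ServiceLedger, totals0: TotalsRow,
                     ledger1: ServiceLedger, totals1: TotalsRow
                     ) -> AttributionRecord:
    """Decompose one class's change into R/τ/S contributions plus δ.

    The baseline epoch defines the model: its MAX-group winner, the
    absorbed constants, and the evaluation point of every partial.  If the
    winner switches between epochs the switch's effect lands in δ and a
    diagnostic is logged.
    """
    constants = fit_constants(ledger0, totals0)
    model = ecosystem_model(constants)

    s0, s1 = totals0.corrected_area, totals1.corrected_area
    x0 = totals0.winner_value / s0 if s0 > 0 else 0.0
    win1 = ledger1.get(totals0.winner_service, 0.0)
    x1 = win1 / s1 if s1 > 0 else 0.0
    state0 = {"R": x0, "tau": totals0.tau, "S": s0}
    state1 = {"R": x1, "tau": totals1.tau, "S": s1}
    dec = decompose_general(model, state0, state1)

    switched = totals1.winner_service != totals0.winner_service
    if switched:
        log.info("MAX-group winner switched %s -> %s for %s/%s",
                 totals0.winner_service, totals1.winner_service,
                 totals0.unit_id, totals0.ecosystem.value)

    rates = contribution_rates(dec.contributions, dec.delta, dec.dY)
    return AttributionRecord(
        unit_id=totals0.unit_id, ecosystem=totals0.ecosystem,
        contributions=dec.contributions, delta=dec.delta,
        dT_model=dec.dY, dT_actual=totals1.total - totals0.total,
        rates=rates, natural_factor=_natural_factor(ledger0,
                                                    totals0.winner_service),
        winner_service=totals0.winner_service,
        elasticities=dec.elasticities, winner_switched=switched)


def attribute_pair(ledgers0: Sequence[ServiceLedger],
                   totals0: Sequence[TotalsRow],
                   ledgers1: Sequence[ServiceLedger],
                   totals1: Sequence[TotalsRow]) -> list[AttributionRecord]:
    """Match (unit, class) rows across two epochs and attribute each."""

    def index(ledgers, rows):
        led = {(l.unit_id, l.ecosystem): l for l in ledgers}
        tot = {(t.unit_id, t.ecosystem): t for t in rows}
        if set(led) != set(tot):
            raise ParameterError("ledger and totals keys disagree")
        return led, tot

    led0, tot0 = index(ledgers0, totals0)
    led1, tot1 = index(ledgers1, totals1)
    if set(led0) != set(led1):
        raise ParameterError(
            "epochs cover different (unit, class) sets; align inputs first")
    out = []
    for key in sorted(led0, key=lambda k: (k[0], k[1].value)):
        out.append(attribute_record(led0[key], tot0[key], led1[key], tot1[key]))
    return out


def contribution_rates(contributions: Mapping[str, float], delta: float,
                       dT: float) -> dict[str, float] | None:
    """Per-driver rates Cr/ΔT with the residual rate closing to 1 exactly.

    Returns None when ΔT = 0 (rates undefined; contributions still stand).
    """
    if dT == 0:
        return None
    rates = {name: contributions[name] / dT for name in contributions}
    rates["delta"] = 1.0 - sum(rates.values())
    return rates


# ---------------------------------------------------------------------------
# multi-ecosystem and regional aggregation
# ---------------------------------------------------------------------------


@dataclass
class AggregateAttribution:
    """Driver contributions to the total change of a set of classes."""

    dT: float
    contributions: dict[str, float]  # "R", "tau", "S", "delta" in sej·yr⁻¹
    rates: dict[str, float] | None  # fractions; None when dT == 0
    by_class: dict[str, float] = field(default_factory=dict)  # class ΔT


def aggregate_attribution(records: Iterable[AttributionRecord]
                          ) -> AggregateAttribution:
    """Weight per-class rates by class total-changes and re-close δ.

    ΔR = Σ ΔT_class·R-rate_class (likewise τ, S); δ contribution is the
    remainder, so contributions always sum to ΔT bit-consistently.  A class
    with undefined rates but nonzero ΔT lands entirely in δ.
    """
    dT = 0.0
    sums = {name: 0.0 for name in DRIVERS}
    by_class: dict[str, float] = {}
    for rec in records:
        dT += rec.dT_actual
        by_class[rec.ecosystem.value] = (
            by_class.get(rec.ecosystem.value, 0.0) + rec.dT_actual)
        if rec.rates is None:
            continue
        for name in DRIVERS:
            sums[name] += rec.dT_actual * rec.rates[name]
    contributions = dict(sums)
    contributions["delta"] = dT - sum(sums.values())
    rates = None
    if dT != 0:
        rates = {name: contributions[name] / dT for name in DRIVERS}
        rates["delta"] = 1.0 - sum(rates.values())
    return AggregateAttribution(dT=dT, contributions=contributions,
                                rates=rates, by_class=by_class)


def round_percent(x: float) -> int:
    """Integer percent of a fraction, rounding half away from zero."""
    v = x * 100.0
    return int(math.floor(abs(v) + 0.5) * (1 if v >= 0 else -1))


def ratio_2dp(x: float) -> float:
    """Two-decimal ratio rendering, truncating toward zero.

    Matches the printed-table convention (e.g. 1.7256 renders as 1.72).
    """
    return math.trunc(x * 100.0) / 100.0


def summary_from_contributions(
    contributions: Mapping[str, Mapping[str, float]],
    region_total_area: Mapping[str, float] | None = None,
    region_eco_area: Mapping[str, float] | None = None,
    class_changes: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Region summary table from per-region driver contributions.

    ``contributions`` maps zone -> {"R","tau","S","delta"} in sej·yr⁻¹
    (an optional "subtotal" overrides the sum).  Emits, per region:
    contributions, subtotal, Ratio (share of the extent change),
    per-area intensities where areas are given, integer-percent driver
    rates, and optional per-class contribution-rate percents.
    """
    zones = [z for z in ZONES if z in contributions] or list(contributions)
    subtotals = {}
    for z in zones:
        c = contributions[z]
        subtotals[z] = c.get("subtotal",
                             sum(c.get(k, 0.0) for k in (*DRIVERS, "delta")))
    extent = sum(subtotals.values())
    rows = []
    for z in zones:
        c = contributions[z]
        sub = subtotals[z]
        row: dict[str, object] = {"region": z}
        for k in DRIVERS:
            row[f"contribution_{k}"] = c.get(k, 0.0)
        row["contribution_delta"] = c.get(
            "delta", sub - sum(c.get(k, 0.0) for k in DRIVERS))
        row["subtotal"] = sub
        row["ratio"] = sub / extent if extent != 0 else math.nan
        row["ratio_pct"] = (round_percent(row["ratio"])
                            if extent != 0 else None)
        for label, areas in (("per_total_area", region_total_area),
                             ("per_eco_area", region_eco_area)):
            if areas is None or z not in areas:
                row[label] = math.nan
            else:
                area = areas[z]
                row[label] = sub / area if area > 0 else math.nan
        if sub != 0:
            for k in DRIVERS:
                row[f"rate_{k}_pct"] = round_percent(c.get(k, 0.0) / sub)
            row["rate_delta_pct"] = round_percent(
                row["contribution_delta"] / sub)
        else:
            for k in (*DRIVERS, "delta"):
                row[f"rate_{k}_pct"] = None
        if class_changes is not None and z in class_changes and sub != 0:
            for cls, d in class_changes[z].items():
                row[f"class_{cls}_pct"] = round_percent(d / sub)
        rows.append(row)
    return pd.DataFrame(rows)


def regional_summary(records: Iterable[AttributionRecord],
                     region_spec: RegionSpec,
                     region_total_area: Mapping[str, float] | None = None,
                     region_eco_area: Mapping[str, float] | None = None,
                     ) -> pd.DataFrame:
    """Aggregate attribution records per precipitation zone (printed-table
    layout: contributions, subtotal, Ratio, per-area intensities, rates)."""
    by_zone: dict[str, list[AttributionRecord]] = {}
    for rec in records:
        by_zone.setdefault(region_spec.zone_of(rec.unit_id), []).append(rec)
    contributions = {}
    class_changes = {}
    for zone, recs in by_zone.items():
        agg = aggregate_attribution(recs)
        contributions[zone] = {**{k: agg.contributions[k] for k in DRIVERS},
                               "delta": agg.contributions["delta"],
                               "subtotal": agg.dT}
        class_changes[zone] = agg.by_class
    return summary_from_contributions(contributions, region_total_area,
                                      region_eco_area, class_changes)


def natural_factor_shares(records: Iterable[AttributionRecord]
                          ) -> pd.DataFrame:
    """Per-unit shares of |Cr_R| mass by natural-factor label.

    Shares normalize to 100% within a unit; the sign of the aggregate Cr_R
    is reported as improvement/deterioration.  Units whose every Cr_R is
    zero are omitted.
    """
    per_unit: dict[str, dict[str, float]] = {}
    signed: dict[str, float] = {}
    for rec in records:
        cr = rec.contributions["R"]
        if cr == 0.0:
            continue
        unit = per_unit.setdefault(rec.unit_id, {})
        unit[rec.natural_factor] = unit.get(rec.natural_factor, 0.0) + abs(cr)
        signed[rec.unit_id] = signed.get(rec.unit_id, 0.0) + cr
    rows = []
    for unit_id in sorted(per_unit):
        mass = per_unit[unit_id]
        total = sum(mass.values())
        for factor in sorted(mass, key=lambda f: -mass[f]):
            rows.append({
                "unit_id": unit_id,
                "natural_factor": factor,
                "share": mass[factor] / total,
                "state": ("improvement" if signed[unit_id] >= 0
                          else "deterioration"),
            })
    return pd.DataFrame(rows,
                        columns=["unit_id", "natural_factor", "share", "state"])
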