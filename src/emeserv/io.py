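"""CSV readers/writers for every exchanged table, plus the pipeline glue.

CSV is the sole interchange format.  Floats are serialized with %.17g so
every table round-trips bit-exactly; nested structures (mineral
proportions, dam lists) use compact ``name:value|…`` / ``a:b:c:d;…``
encodings inside a single cell.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from . import emergy_base, totals as totals_mod
from .attribution import AttributionRecord, attribute_pair
from .emergy_base import OPEN_WATER_CLASSES, vegetation_fraction
from .parameters import (
    CognitionInputs,
    DamRecord,
    EcosystemClass,
    ParameterError,
    RegionSpec,
    RenewableDrivers,
    SoilProfile,
    UnitRecord,
)
from .services import ServiceLedger, ServiceValue, account_record
from .totals import TotalsRow

__all__ = [
    "write_records", "read_records",
    "write_regions", "read_regions",
    "write_cognition", "read_cognition",
    "write_ledgers", "read_ledgers",
    "write_totals", "read_totals",
    "write_attribution", "read_attribution",
    "account", "compute_vf_support",
]

FLOAT_FMT = "%.17g"

_RENEW_FIELDS = ("solar", "tidal", "geothermal", "wave", "wind",
                 "rain_chemical", "runoff_geopotential", "runoff_chemical")


def _enc_map(d: dict) -> str:
    return "|".join(f"{k}:{v!r}" for k, v in sorted(d.items()))


def _dec_map(s: str) -> dict[str, float]:
    if not isinstance(s, str) or not s:
        return {}
    out = {}
    for item in s.split("|"):
        k, v = item.split(":")
        out[k] = float(v)
    return out


def _enc_dams(dams: Sequence[DamRecord]) -> str:
    return ";".join(
        f"{d.catchment_area!r}:{d.rainfall!r}:{d.deviation_rate!r}:{d.position_x!r}"
        for d in dams)


def _dec_dams(s: str) -> list[DamRecord]:
    if not isinstance(s, str) or not s:
        return []
    out = []
    for item in s.split(";"):
        c, r, d, x = (float(v) for v in item.split(":"))
        out.append(DamRecord(c, r, d, x))
    return out


def write_records(path, records: Iterable[UnitRecord]) -> None:
    rows = []
    for r in records:
        row = {
            "unit_id": r.unit_id, "ecosystem": r.ecosystem.value,
            "epoch": r.epoch, "raw_area": r.raw_area, "ndvi": r.ndvi,
            "precipitation": r.precipitation,
            "evapotranspiration": r.evapotranspiration,
            "elevation": r.elevation, "npp": r.npp,
            "carbon_pool": r.carbon_pool,
            "carbon_turnover": r.carbon_turnover,
            "infiltration_coeff": r.infiltration_coeff,
            "eutrophic": int(r.eutrophic),
            "soil_bulk_density": r.soil.bulk_density,
            "soil_depth": r.soil.depth,
            "soil_som_fraction": r.soil.som_fraction,
            "soil_retention_amount": r.soil.retention_amount,
            "soil_minerals": _enc_map(dict(r.soil.mineral_proportions)),
            "dams": _enc_dams(r.dams),
        }
        for f in _RENEW_FIELDS:
            row[f"renew_{f}"] = getattr(r.renewable, f)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_records(path) -> list[UnitRecord]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                     dtype={"unit_id": str, "epoch": str})
    out = []
    for _, row in df.iterrows():
        out.append(UnitRecord(
            unit_id=row["unit_id"],
            ecosystem=EcosystemClass(row["ecosystem"]),
            epoch=row["epoch"],
            raw_area=float(row["raw_area"]), ndvi=float(row["ndvi"]),
            precipitation=float(row["precipitation"]),
            evapotranspiration=float(row["evapotranspiration"]),
            elevation=float(row["elevation"]), npp=float(row["npp"]),
            carbon_pool=float(row["carbon_pool"]),
            carbon_turnover=float(row["carbon_turnover"]),
            infiltration_coeff=float(row["infiltration_coeff"]),
            eutrophic=bool(int(row["eutrophic"])),
            soil=SoilProfile(
                bulk_density=float(row["soil_bulk_density"]),
                depth=float(row["soil_depth"]),
                mineral_proportions=_dec_map(row["soil_minerals"]),
                som_fraction=float(row["soil_som_fraction"]),
                retention_amount=float(row["soil_retention_amount"])),
            renewable=RenewableDrivers(
                **{f: float(row[f"renew_{f}"]) for f in _RENEW_FIELDS}),
            dams=_dec_dams(row["dams"]),
        ))
    return out


def write_regions(path, regions: RegionSpec) -> None:
    pd.DataFrame(sorted(regions.zones.items()),
                 columns=["unit_id", "zone"]).to_csv(path, index=False)


def read_regions(path) -> RegionSpec:
    df = pd.read_csv(path, dtype=str)
    return RegionSpec(zones=dict(zip(df["unit_id"], df["zone"])))


def write_cognition(path, cognition: dict[str, CognitionInputs]) -> None:
    rows = [{"epoch": e, "health_expenditure": c.health_expenditure,
             "population": c.population,
             "emergy_money_ratio": c.emergy_money_ratio}
            for e, c in sorted(cognition.items())]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cognition(path) -> dict[str, CognitionInputs]:
    df = pd.read_csv(path, dtype={"epoch": str}, float_precision="round_trip")
    return {row["epoch"]: CognitionInputs(
        health_expenditure=float(row["health_expenditure"]),
        population=float(row["population"]),
        emergy_money_ratio=float(row["emergy_money_ratio"]))
        for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# accounting pipeline
# ---------------------------------------------------------------------------


def compute_vf_support(records: Sequence[UnitRecord]
                       ) -> dict[EcosystemClass, tuple[float, float]]:
    """Per-class NDVI (min, max) support over the whole extent."""
    by_class: dict[EcosystemClass, list[float]] = {}
    for r in records:
        by_class.setdefault(r.ecosystem, []).append(r.ndvi)
    return {eco: (min(vals), max(vals)) for eco, vals in by_class.items()}


def account(records: Sequence[UnitRecord], params, factors,
            cognition: CognitionInputs, *,
            water_vf_one: bool = True,
            ndvi_support: tuple[float, float] | None = None,
            strict_dams: bool = False) -> list[ServiceLedger]:
    """Correct areas and compute every applicable service per record.

    All records must share one epoch.  The NDVI support defaults to the
    per-class extent min/max; pass a fixed (min, max) to override.
    """
    epochs = {r.epoch for r in records}
    if len(epochs) > 1:
        raise ParameterError(f"mixed epochs in one accounting call: {sorted(epochs)}")
    support = (None if ndvi_support is not None
               else compute_vf_support(records))
    ledgers = []
    for r in records:
        if water_vf_one and r.ecosystem in OPEN_WATER_CLASSES:
            vf = 1.0
        else:
            lo, hi = (ndvi_support if ndvi_support is not None
                      else support[r.ecosystem])
            vf = vegetation_fraction(r.ndvi, lo, hi)
        corrected = r.raw_area * vf
        ledgers.append(account_record(r, corrected, vf, params, factors,
                                      cognition, strict_dams=strict_dams))
    return ledgers


# ---------------------------------------------------------------------------
# ledger / totals / attribution tables
# ---------------------------------------------------------------------------


def write_ledgers(ledger_path, meta_path,
                  ledgers: Iterable[ServiceLedger]) -> None:
    srows, mrows = [], []
    for led in ledgers:
        mrows.append({
            "unit_id": led.unit_id, "ecosystem": led.ecosystem.value,
            "epoch": led.epoch, "vf": led.vf,
            "corrected_area": led.corrected_area, "tau": led.tau,
            "max_renewable": led.max_renewable.value,
            "renew_winner": led.max_renewable.winner,
            "natural_factor": led.max_renewable.natural_factor,
            "dam_position": ("" if led.dam_position is None
                             else repr(led.dam_position)),
        })
        for name in sorted(led.services):
            sv = led.services[name]
            srows.append({"unit_id": led.unit_id,
                          "ecosystem": led.ecosystem.value,
                          "epoch": led.epoch, "service": name,
                          "component": "total", "value": sv.value})
            for comp in sorted(sv.components):
                srows.append({"unit_id": led.unit_id,
                              "ecosystem": led.ecosystem.value,
                              "epoch": led.epoch, "service": name,
                              "component": comp,
                              "value": sv.components[comp]})
    pd.DataFrame(srows).to_csv(ledger_path, index=False, float_format=FLOAT_FMT)
    pd.DataFrame(mrows).to_csv(meta_path, index=False, float_format=FLOAT_FMT)


def read_ledgers(ledger_path, meta_path) -> list[ServiceLedger]:
    sdf = pd.read_csv(ledger_path, dtype={"unit_id": str, "epoch": str},
                      float_precision="round_trip")
    mdf = pd.read_csv(meta_path, keep_default_na=False,
                      float_precision="round_trip",
                      dtype={"unit_id": str, "epoch": str,
                             "dam_position": str})
    grouped: dict[tuple, dict[str, ServiceValue]] = {}
    for (u, e, ep, svc), g in sdf.groupby(
            ["unit_id", "ecosystem", "epoch", "service"], sort=False):
        comps = {row["component"]: float(row["value"])
                 for _, row in g.iterrows()}
        total = comps.pop("total")
        grouped.setdefault((u, e, ep), {})[svc] = ServiceValue(
            svc, total, components=comps)
    out = []
    for _, row in mdf.iterrows():
        key = (row["unit_id"], row["ecosystem"], row["epoch"])
        out.append(ServiceLedger(
            unit_id=row["unit_id"],
            ecosystem=EcosystemClass(row["ecosystem"]),
            epoch=row["epoch"], corrected_area=float(row["corrected_area"]),
            vf=float(row["vf"]), tau=float(row["tau"]),
            max_renewable=emergy_base.MaxRenewableResult(
                value=float(row["max_renewable"]),
                winner=row["renew_winner"],
                natural_factor=row["natural_factor"]),
            services=grouped.get(key, {}),
            dam_position=(None if row["dam_position"] == ""
                          else float(row["dam_position"])),
        ))
    return out


def write_totals(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_totals(path) -> list[TotalsRow]:
    df = pd.read_csv(path, dtype={"unit_id": str, "epoch": str},
                     float_precision="round_trip")
    return [TotalsRow(
        unit_id=row["unit_id"], ecosystem=EcosystemClass(row["ecosystem"]),
        epoch=row["epoch"], total=float(row["total"]),
        winner_service=row["winner_service"],
        winner_value=float(row["winner_value"]),
        case_label=row["case_label"],
        corrected_area=float(row["corrected_area"]), tau=float(row["tau"]))
        for _, row in df.iterrows()]


def write_attribution(path, records: Iterable[AttributionRecord]) -> None:
    rows = []
    for r in records:
        row = {"unit_id": r.unit_id, "ecosystem": r.ecosystem.value,
               "cr_R": r.contributions["R"], "cr_tau": r.contributions["tau"],
               "cr_S": r.contributions["S"], "delta": r.delta,
               "dT_model": r.dT_model, "dT_actual": r.dT_actual,
               "natural_factor": r.natural_factor,
               "winner_service": r.winner_service,
               "winner_switched": int(r.winner_switched)}
        for k in ("R", "tau", "S", "delta"):
            row[f"rate_{k}"] = "" if r.rates is None else repr(r.rates[k])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_attribution(path) -> list[AttributionRecord]:
    df = pd.read_csv(path, keep_default_na=False,
                     float_precision="round_trip",
                     dtype={"unit_id": str, "rate_R": str, "rate_tau": str,
                            "rate_S": str, "rate_delta": str})
    out = []
    for _, row in df.iterrows():
        rates = None
        if row["rate_R"] != "":
            rates = {k: float(row[f"rate_{k}"])
                     for k in ("R", "tau", "S", "delta")}
        out.append(AttributionRecord(
            unit_id=row["unit_id"],
            ecosystem=EcosystemClass(row["ecosystem"]),
            contributions={"R": float(row["cr_R"]),
                           "tau": float(row["cr_tau"]),
                           "S": float(row["cr_S"])},
            delta=float(row["delta"]), dT_model=float(row["dT_model"]),
            dT_actual=float(row["dT_actual"]), rates=rates,
            natural_factor=row["natural_factor"],
            winner_service=row["winner_service"],
            winner_switched=bool(int(row["winner_switched"]))))
    return out


def run_pipeline(fixture, *, ndvi_support=None):
    """Account → totals → attribution on a two-epoch fixture; returns
    (ledgers, totals rows, attribution records)."""
    (e0, e1) = sorted(fixture.records)
    led0 = account(fixture.records[e0], fixture.params, fixture.factors,
                   fixture.cognition[e0], ndvi_support=ndvi_support)
    led1 = account(fixture.records[e1], fixture.params, fixture.factors,
                   fixture.cognition[e1], ndvi_support=ndvi_support)
    tot0 = [totals_mod.total_record(l) for l in led0]
    tot1 = [totals_mod.total_record(l) for l in led1]
    recs = attribute_pair(led0, tot0, led1, tot1)
    return {"ledgers": (led0, led1), "totals": (tot0, tot1),
            "attribution": recs}
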