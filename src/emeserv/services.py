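"""The eleven ecosystem services as annual emergy flows (sej·yr⁻¹).

Each service function takes a unit record plus the derived quantities it
needs (corrected area, renewable MAX) and returns a :class:`ServiceValue`
whose ``components`` break out the published sub-terms (human-health vs
ecosystem-quality, organic vs mineral, rain vs mountain).  Applicability is
enforced strictly: a service that does not exist for a class raises
:class:`ApplicabilityError` instead of silently returning zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .emergy_base import MaxRenewableResult, max_renewable
from .parameters import (
    CognitionInputs,
    EcosystemClass,
    EmergyParams,
    ImpactFactors,
    ParameterError,
    UnitRecord,
)

__all__ = [
    "ApplicabilityError",
    "ServiceValue",
    "ServiceLedger",
    "SERVICE_APPLICABILITY",
    "applicable_services",
    "tau_h",
    "carbon_sequestration",
    "soil_building",
    "sediment_building",
    "groundwater_recharge",
    "air_purification",
    "water_purification",
    "soil_retention",
    "microclimate_regulation",
    "materials_transport",
    "hydropower_potential",
    "climate_regulation",
    "account_record",
]

log = logging.getLogger(__name__)


class ApplicabilityError(ValueError):
    """Service requested on an ecosystem class it does not exist for."""


@dataclass(frozen=True)
class ServiceValue:
    service: str
    value: float  # sej·yr⁻¹
    components: dict[str, float] = field(default_factory=dict)
    meta: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ParameterError(
                f"service {self.service} produced a negative value: {self.value}")


_TERRESTRIAL = ("NPP", "CS", "SB", "GR", "AP", "SR", "MR", "CR")
_AQUATIC = ("NPP", "CS", "SBa", "GR", "AP", "WP", "MR", "CR")
_RIVER = _AQUATIC + ("MT", "HG")

#: service applicability per ecosystem class; services absent from a class
#: are absent from its ledger, never stored as zero.
SERVICE_APPLICABILITY: dict[EcosystemClass, tuple[str, ...]] = {
    **{c: _TERRESTRIAL for c in EcosystemClass if c.is_terrestrial},
    **{c: _AQUATIC for c in EcosystemClass
       if c.is_aquatic and not c.is_river},
    EcosystemClass.RIVER: _RIVER,
}


def applicable_services(ecosystem: EcosystemClass) -> tuple[str, ...]:
    return SERVICE_APPLICABILITY[ecosystem]


def _require(ecosystem: EcosystemClass, service: str) -> None:
    if service not in SERVICE_APPLICABILITY[ecosystem]:
        raise ApplicabilityError(
            f"service {service} is not applicable to class {ecosystem.value}")


def tau_h(cognition: CognitionInputs) -> float:
    """Per-capita health-expenditure emergy τ_H = I·EmR / Pop (sej·cap⁻¹)."""
    return (cognition.health_expenditure * cognition.emergy_money_ratio
            / cognition.population)


def carbon_sequestration(record: UnitRecord, corrected_area: float,
                         em_npp: float) -> ServiceValue:
    """Carbon sequestration via the NPP-derived carbon UEV.

    UEV_cs = EmNPP / (S′ · NPP); EmCS = (C/T) · S′ · UEV_cs, which
    telescopes to EmNPP · C / (T · NPP).
    """
    _require(record.ecosystem, "CS")
    if record.carbon_pool == 0.0:
        return ServiceValue("CS", 0.0)
    if record.npp <= 0.0:
        raise ParameterError(
            "carbon UEV undefined: NPP = 0 with a nonzero carbon pool")
    if corrected_area <= 0.0:
        return ServiceValue("CS", 0.0)
    uev_cs = em_npp / (corrected_area * record.npp)
    value = (record.carbon_pool / record.carbon_turnover) * corrected_area * uev_cs
    return ServiceValue("CS", value, meta={"uev_cs": uev_cs})


def soil_building(record: UnitRecord, corrected_area: float, em_npp: float,
                  params: EmergyParams) -> ServiceValue:
    """Soil building = organic-matter term + winning mineral term."""
    _require(record.ecosystem, "SB")
    k1 = params.litter_biomass_ratio.get(record.ecosystem.value, 0.0)
    organic = em_npp * k1 * params.detritus_carbon_fraction
    c = params.constants
    soil = record.soil
    best = 0.0
    winner = None
    for name in sorted(soil.mineral_proportions):
        pm = soil.mineral_proportions[name]
        try:
            uev = params.uev_minerals[name]
        except KeyError:
            raise ParameterError(f"no mineral UEV for species {name!r}") from None
        term = (pm * soil.bulk_density * soil.depth * corrected_area
                * c["mineral_mass_fraction"] * c["m2_to_cm2"]
                / c["mineral_turnover"]) * uev
        if term > best:
            best, winner = term, name
    return ServiceValue("SB", organic + best,
                        components={"organic": organic, "mineral": best},
                        meta={"winning_mineral": winner})


def sediment_building(record: UnitRecord, corrected_area: float,
                      params: EmergyParams) -> ServiceValue | None:
    """Organic-sediment deposition in non-eutrophic aquatic ecosystems.

    Returns None (service absent) for eutrophic records.
    """
    _require(record.ecosystem, "SBa")
    if record.eutrophic:
        log.info("record %s is eutrophic; sediment building excluded",
                 record.unit_id)
        return None
    c = params.constants
    om = c["deposition_npp_ratio"] * record.npp  # g·m⁻²·yr⁻¹
    k2 = params.g_to_kcal.get(record.ecosystem.value, 0.0)
    value = (om * c["aquatic_absorption"] * k2 * c["kcal_to_joule"]
             * corrected_area * params.uev["uev_organic_sediment"])
    return ServiceValue("SBa", value, meta={"om_deposition": om})


def groundwater_recharge(record: UnitRecord, corrected_area: float,
                         params: EmergyParams) -> ServiceValue:
    """Precipitation infiltrating to groundwater, valued at the rain UEV."""
    _require(record.ecosystem, "GR")
    c = params.constants
    value = (record.precipitation * corrected_area * c["water_density"]
             * record.infiltration_coeff * c["kg_to_g"]
             * params.uev["uev_rain_chemical"])
    return ServiceValue("GR", value)


def air_purification(record: UnitRecord, corrected_area: float,
                     factors: ImpactFactors, tau: float,
                     em_sp: float, params: EmergyParams) -> ServiceValue:
    """Air-pollutant uptake valued through DALY (health) and PDF (quality)."""
    _require(record.ecosystem, "AP")
    area_ha = corrected_area * params.constants["m2_to_ha"]
    hh = 0.0
    eq = 0.0
    for name in sorted(factors.air):
        f = factors.air[name]
        m = f.uptake.get(record.ecosystem.value, 0.0)
        hh += m * area_ha * f.daly * tau
        eq += m * f.pdf * em_sp
    return ServiceValue("AP", hh + eq, components={"HH": hh, "EQ": eq})


def water_purification(record: UnitRecord, corrected_area: float,
                       factors: ImpactFactors, tau: float,
                       em_sp: float, params: EmergyParams) -> ServiceValue:
    """Heavy-metal self-purification of aquatic ecosystems.

    The dimensional bridge between mg·kg⁻¹ removal and the NPP flux is the
    declared ``wp_bridge`` constant, applied once per term.
    """
    _require(record.ecosystem, "WP")
    bridge = params.constants["wp_bridge"]
    hh = 0.0
    eq = 0.0
    for name in sorted(factors.water):
        f = factors.water[name]
        m = f.removal.get(record.ecosystem.value, 0.0)
        common = m * record.npp * bridge / f.turnover
        hh += common * corrected_area * f.daly * tau
        eq += common * f.pdf * em_sp
    return ServiceValue("WP", hh + eq, components={"HH": hh, "EQ": eq})


def soil_retention(record: UnitRecord, corrected_area: float,
                   params: EmergyParams) -> ServiceValue:
    """Erosion prevented by vegetated cover, valued at the soil UEV."""
    _require(record.ecosystem, "SR")
    c = params.constants
    kr1 = params.g_to_kcal.get("soil")
    if kr1 is None:
        raise ParameterError("missing g_to_kcal['soil'] (kr1)")
    area_ha = corrected_area * c["m2_to_ha"]
    value = (record.soil.retention_amount * area_ha * record.soil.som_fraction
             * c["t_to_g"] * kr1 * c["kcal_to_joule"] * params.uev["uev_soil"])
    return ServiceValue("SR", value)


def microclimate_regulation(record: UnitRecord, corrected_area: float,
                            params: EmergyParams) -> ServiceValue:
    """Evapotranspiration valued at the transpired-water UEV."""
    _require(record.ecosystem, "MR")
    value = (record.evapotranspiration * corrected_area
             * params.uev["uev_transpired_water"])
    return ServiceValue("MR", value)


def materials_transport(record: UnitRecord, corrected_area: float,
                        params: EmergyParams) -> ServiceValue:
    """Geopotential-driven material transport in rivers."""
    _require(record.ecosystem, "MT")
    c = params.constants
    value = (corrected_area * record.precipitation * c["water_density"]
             * c["runoff_rate"] * record.elevation * c["gravity"]
             * params.uev["uev_runoff_geopotential"])
    return ServiceValue("MT", value)


def hydropower_potential(record: UnitRecord,
                         params: EmergyParams) -> ServiceValue:
    """Hydropower potential: per-dam rain term + mountain-building term."""
    _require(record.ecosystem, "HG")
    c = params.constants
    rain = 0.0
    mountain = 0.0
    for dam in record.dams:
        rain += (dam.catchment_area * dam.rainfall * c["water_density"]
                 * c["hg_mass_conversion"] * params.uev["uev_rain_hydro"])
        mountain += (dam.catchment_area * dam.deviation_rate * c["m3_to_cm3"]
                     * params.mountain_density * params.uev["uev_mountain"])
    return ServiceValue("HG", rain + mountain,
                        components={"rain": rain, "mountain": mountain})


def climate_regulation(record: UnitRecord, corrected_area: float,
                       factors: ImpactFactors, tau: float,
                       em_sp: float) -> ServiceValue:
    """Greenhouse-gas sequestration valued through DALY/PDF per lifetime."""
    _require(record.ecosystem, "CR")
    hh = 0.0
    eq = 0.0
    for name in sorted(factors.greenhouse):
        f = factors.greenhouse[name]
        cseq = f.sequestration.get(record.ecosystem.value, 0.0)
        hh += cseq * (f.daly / f.lifetime) * corrected_area * tau
        eq += cseq * (f.pdf / f.lifetime) * em_sp
    return ServiceValue("CR", hh + eq, components={"HH": hh, "EQ": eq})


@dataclass
class ServiceLedger:
    """All applicable services of one record, with renewable diagnostics."""

    unit_id: str
    ecosystem: EcosystemClass
    epoch: str
    corrected_area: float
    vf: float
    tau: float
    max_renewable: MaxRenewableResult
    services: dict[str, ServiceValue]
    dam_position: float | None = None  # emergy-weighted X for rivers

    def value(self, service: str) -> float:
        return self.services[service].value

    def get(self, service: str, default: float = 0.0) -> float:
        sv = self.services.get(service)
        return sv.value if sv is not None else default


def _dam_position(record: UnitRecord, params: EmergyParams, *,
                  strict: bool = False) -> float | None:
    """Emergy-weighted mean dam position X for a river record."""
    if not record.dams:
        return None
    positions = {d.position_x for d in record.dams}
    if strict and len(positions) > 1:
        raise ParameterError(
            f"river {record.unit_id!r} has dams at conflicting positions "
            f"{sorted(positions)} (strict multi-dam mode)")
    c = params.constants
    weights = []
    for dam in record.dams:
        w = (dam.catchment_area * dam.rainfall * c["water_density"]
             * c["hg_mass_conversion"] * params.uev["uev_rain_hydro"]
             + dam.catchment_area * dam.deviation_rate * c["m3_to_cm3"]
             * params.mountain_density * params.uev["uev_mountain"])
        weights.append(w)
    total = sum(weights)
    if total == 0.0:
        return float(sum(d.position_x for d in record.dams) / len(record.dams))
    x = sum(w * d.position_x for w, d in zip(weights, record.dams)) / total
    return float(x)


def account_record(record: UnitRecord, corrected_area: float, vf: float,
                   params: EmergyParams, factors: ImpactFactors,
                   cognition: CognitionInputs, *,
                   strict_dams: bool = False) -> ServiceLedger:
    """Compute every applicable service for one record."""
    maxr = max_renewable(record.renewable)
    em_npp = maxr.value
    em_sp = maxr.value  # species-support emergy = local renewables
    tau = tau_h(cognition)
    eco = record.ecosystem

    services: dict[str, ServiceValue] = {
        "NPP": ServiceValue("NPP", em_npp,
                            meta={"winner": maxr.winner,
                                  "natural_factor": maxr.natural_factor}),
        "CS": carbon_sequestration(record, corrected_area, em_npp),
        "GR": groundwater_recharge(record, corrected_area, params),
        "AP": air_purification(record, corrected_area, factors, tau, em_sp,
                               params),
        "MR": microclimate_regulation(record, corrected_area, params),
        "CR": climate_regulation(record, corrected_area, factors, tau, em_sp),
    }
    if eco.is_terrestrial:
        services["SB"] = soil_building(record, corrected_area, em_npp, params)
        services["SR"] = soil_retention(record, corrected_area, params)
    else:
        sba = sediment_building(record, corrected_area, params)
        if sba is not None:
            services["SBa"] = sba
        services["WP"] = water_purification(record, corrected_area, factors,
                                            tau, em_sp, params)
    if eco.is_river:
        services["MT"] = materials_transport(record, corrected_area, params)
        services["HG"] = hydropower_potential(record, params)

    return ServiceLedger(
        unit_id=record.unit_id, ecosystem=eco, epoch=record.epoch,
        corrected_area=corrected_area, vf=vf, tau=tau, max_renewable=maxr,
        services=services,
        dam_position=_dam_position(record, params, strict=strict_dams)
        if eco.is_river else None,
    )
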