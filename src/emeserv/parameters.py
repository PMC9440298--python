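"""Domain types, physical constants and user-supplied parameter tables.

All quantities are kept in canonical SI-ish internal units: areas in m²,
precipitation in m·yr⁻¹, emergy flows in sej·yr⁻¹.  Unit conversions
(ha↔m², kg↔g, t↔g, m³↔cm³, kcal↔J) live in the parameter layer as named
constants and are applied exactly once inside the service formulas; they
are never re-derived ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping

import yaml

__all__ = [
    "EcosystemClass",
    "SoilProfile",
    "RenewableDrivers",
    "DamRecord",
    "UnitRecord",
    "EmergyParams",
    "AirPollutant",
    "WaterPollutant",
    "GreenhouseGas",
    "ImpactFactors",
    "CognitionInputs",
    "RegionSpec",
    "ZONES",
    "ParameterError",
    "load_params",
    "save_params",
    "demo_params",
]


class ParameterError(ValueError):
    """Raised for missing/invalid parameter-table entries."""


class EcosystemClass(str, Enum):
    """The nine ecosystem classes under study."""

    FOREST = "F1"
    SHRUB = "F2"
    GRASS_HIGH = "G1"
    GRASS_MEDIUM = "G2"
    GRASS_LOW = "G3"
    WETLAND = "A1"
    LAKE = "A2"
    RESERVOIR_POND = "A3"
    RIVER = "A4"

    @property
    def is_aquatic(self) -> bool:
        return self.value.startswith("A")

    @property
    def is_terrestrial(self) -> bool:
        return not self.is_aquatic

    @property
    def is_river(self) -> bool:
        return self is EcosystemClass.RIVER

    @property
    def is_grassland(self) -> bool:
        return self.value.startswith("G")


ZONES = ("north_of_400mm", "between_400_800mm", "south_of_800mm")


@dataclass(frozen=True)
class SoilProfile:
    """Topsoil description used by the soil building / retention services."""

    bulk_density: float = 1.3  # g·cm⁻³
    depth: float = 20.0  # cm
    mineral_proportions: Mapping[str, float] = field(default_factory=dict)
    som_fraction: float = 0.02  # fraction
    retention_amount: float = 0.0  # t·ha⁻¹·yr⁻¹

    def __post_init__(self) -> None:
        if self.bulk_density <= 0:
            raise ParameterError("soil bulk_density must be > 0")
        if self.depth <= 0:
            raise ParameterError("soil depth must be > 0")
        for name, p in self.mineral_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"mineral proportion {name!r} outside [0,1]: {p}")
        if not 0.0 <= self.som_fraction <= 1.0:
            raise ParameterError("som_fraction outside [0,1]")
        if self.retention_amount < 0:
            raise ParameterError("retention_amount must be >= 0")


#: candidate order of the renewable-emergy MAX rule; ties break toward the
#: earlier entry.  The first candidate is the grouped solar+tidal+geothermal
#: term.
RENEWABLE_ORDER = (
    "grouped",
    "wave",
    "wind",
    "rain_chemical",
    "runoff_geopotential",
    "runoff_chemical",
)

#: physical natural factor underlying each renewable source, used by the
#: attribution dispatch.
RENEWABLE_NATURAL_FACTOR = {
    "grouped": "insolation",
    "wave": "wind",
    "wind": "wind",
    "rain_chemical": "precipitation",
    "runoff_geopotential": "elevation",
    "runoff_chemical": "precipitation",
}


@dataclass(frozen=True)
class RenewableDrivers:
    """Per-source annual renewable emergy flows (sej·yr⁻¹)."""

    solar: float = 0.0
    tidal: float = 0.0
    geothermal: float = 0.0
    wave: float = 0.0
    wind: float = 0.0
    rain_chemical: float = 0.0
    runoff_geopotential: float = 0.0
    runoff_chemical: float = 0.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ParameterError(f"renewable flow {name!r} must be >= 0, got {v}")

    @property
    def grouped(self) -> float:
        """Sum of the solar, tidal and geothermal terms."""
        return self.solar + self.tidal + self.geothermal

    def candidates(self) -> dict[str, float]:
        """The six MAX-rule candidates in their fixed tie-break order."""
        return {
            "grouped": self.grouped,
            "wave": self.wave,
            "wind": self.wind,
            "rain_chemical": self.rain_chemical,
            "runoff_geopotential": self.runoff_geopotential,
            "runoff_chemical": self.runoff_chemical,
        }


@dataclass(frozen=True)
class DamRecord:
    """One hydropower dam on a river record."""

    catchment_area: float  # m²
    rainfall: float  # m·yr⁻¹
    deviation_rate: float  # m·yr⁻¹ (mountain-building uplift)
    position_x: float  # fraction of river length in [0,1]

    def __post_init__(self) -> None:
        if self.catchment_area < 0:
            raise ParameterError("dam catchment_area must be >= 0")
        if not 0.0 <= self.position_x <= 1.0:
            raise ParameterError(f"dam position_x outside [0,1]: {self.position_x}")


@dataclass
class UnitRecord:
    """One spatial unit × ecosystem class × epoch with its physical drivers."""

    unit_id: str
    ecosystem: EcosystemClass
    epoch: str
    raw_area: float  # m²
    ndvi: float = 0.0
    precipitation: float = 0.0  # m·yr⁻¹
    evapotranspiration: float = 0.0  # g·m⁻²·yr⁻¹ water flux
    elevation: float = 0.0  # m
    npp: float = 0.0  # gC·m⁻²·yr⁻¹
    carbon_pool: float = 0.0  # gC·m⁻²
    carbon_turnover: float = 1.0  # yr
    infiltration_coeff: float = 0.0  # fraction
    soil: SoilProfile = field(default_factory=SoilProfile)
    eutrophic: bool = False
    renewable: RenewableDrivers = field(default_factory=RenewableDrivers)
    dams: list[DamRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.ecosystem, str):
            self.ecosystem = EcosystemClass(self.ecosystem)
        if self.raw_area < 0:
            raise ParameterError(f"raw_area must be >= 0, got {self.raw_area}")
        if not -1.0 <= self.ndvi <= 1.0:
            raise ParameterError(f"ndvi outside [-1,1]: {self.ndvi}")
        for name in ("precipitation", "evapotranspiration", "npp", "carbon_pool"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.carbon_turnover <= 0:
            raise ParameterError("carbon_turnover must be > 0")
        if not 0.0 <= self.infiltration_coeff <= 1.0:
            raise ParameterError("infiltration_coeff outside [0,1]")
        if self.dams and not self.ecosystem.is_river:
            raise ParameterError("dams are only valid on river records")


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

#: UEV keys required in every parameter set (all sej per g or per J).
_UEV_KEYS = (
    "uev_rain_chemical",      # UEV_w, groundwater recharge, sej·g⁻¹
    "uev_rain_hydro",         # UEV_r, hydropower rain term, sej·g⁻¹
    "uev_transpired_water",   # UEV_et, sej·g⁻¹
    "uev_soil",               # UEV_sl, sej·J⁻¹
    "uev_mountain",           # UEV_m, sej·g⁻¹
    "uev_runoff_geopotential",  # UEV_rgeo, sej·J⁻¹
    "uev_organic_sediment",   # UEV_om, sej·J⁻¹
)

# defaults printed in the method text; everything else is user-supplied.
_PRINTED_DEFAULTS = {
    "runoff_rate": 0.25,          # kr
    "mineral_mass_fraction": 0.95,  # R
    "mineral_turnover": 1000.0,   # yr
    "aquatic_absorption": 0.78,   # k1 (sediment building)
    "deposition_npp_ratio": 0.3037,  # k4 (sediment building)
    "kcal_to_joule": 4186.0,
    "water_density": 1000.0,      # kg·m⁻³
    "gravity": 9.8,               # m·s⁻²
    "kg_to_g": 1000.0,
    "t_to_g": 1.0e6,
    "m2_to_cm2": 1.0e4,
    "m2_to_ha": 1.0e-4,
    "m3_to_cm3": 1.0e6,
    "wp_bridge": 1.0,             # dimensional bridge of the heavy-metal chain
    "hg_mass_conversion": 1000.0,  # kg→g bridge in the hydropower rain term
}

_FRACTION_KEYS = (
    "mineral_mass_fraction",
    "aquatic_absorption",
    "deposition_npp_ratio",
    "runoff_rate",
)


@dataclass
class EmergyParams:
    """Unit emergy values, conversion constants and per-class ratios."""

    uev: dict[str, float]
    uev_minerals: dict[str, float]  # per mineral species, sej·g⁻¹
    litter_biomass_ratio: dict[str, float]  # k1_i per class code
    detritus_carbon_fraction: float  # k2
    g_to_kcal: dict[str, float]  # per aquatic class code (k2_i) + soil kr1 under "soil"
    mountain_density: float  # ρ_m, g·cm⁻³
    constants: dict[str, float] = field(default_factory=lambda: dict(_PRINTED_DEFAULTS))

    def __post_init__(self) -> None:
        for key in _UEV_KEYS:
            if key not in self.uev:
                raise ParameterError(f"missing UEV key: {key!r}")
        for key, v in {**self.uev, **self.uev_minerals}.items():
            if v <= 0:
                raise ParameterError(f"UEV {key!r} must be > 0, got {v}")
        merged = dict(_PRINTED_DEFAULTS)
        merged.update(self.constants)
        self.constants = merged
        for key in _FRACTION_KEYS:
            if not 0.0 <= self.constants[key] <= 1.0:
                raise ParameterError(f"constant {key!r} outside [0,1]")
        for key, v in self.constants.items():
            if v < 0:
                raise ParameterError(f"constant {key!r} must be >= 0")
        if self.mountain_density <= 0:
            raise ParameterError("mountain_density must be > 0")
        if not 0.0 <= self.detritus_carbon_fraction <= 1.0:
            raise ParameterError("detritus_carbon_fraction outside [0,1]")
        for cls, v in self.litter_biomass_ratio.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"litter_biomass_ratio[{cls!r}] outside [0,1]")


@dataclass(frozen=True)
class AirPollutant:
    """Uptake/damage factors for one airborne pollutant."""

    uptake: Mapping[str, float]  # kg·ha⁻¹·yr⁻¹ per ecosystem class code
    daly: float  # cap·yr·kg⁻¹
    pdf: float  # PDF·ha·yr·kg⁻¹


@dataclass(frozen=True)
class WaterPollutant:
    """Removal/damage factors for one heavy metal."""

    removal: Mapping[str, float]  # mg·kg⁻¹ per aquatic class code
    daly: float
    pdf: float
    turnover: float  # yr

    def __post_init__(self) -> None:
        if self.turnover <= 0:
            raise ParameterError("water pollutant turnover must be > 0")


@dataclass(frozen=True)
class GreenhouseGas:
    """Sequestration/damage factors for one greenhouse gas."""

    sequestration: Mapping[str, float]  # kg·m⁻²·yr⁻¹ per ecosystem class code
    daly: float
    pdf: float
    lifetime: float  # yr

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ParameterError("greenhouse gas lifetime must be > 0")


AIR_POLLUTANTS = ("SO2", "fluoride", "NOx", "CO", "O3", "PM10", "PM2.5")
WATER_POLLUTANTS = ("Cr", "Ni", "Cu", "Mn", "Zn", "Cd", "Pb")
GREENHOUSE_GASES = ("CO2", "CH4", "NOx", "HFC")


@dataclass
class ImpactFactors:
    """DALY/PDF impact-factor tables for air, water and greenhouse gases."""

    air: dict[str, AirPollutant]
    water: dict[str, WaterPollutant]
    greenhouse: dict[str, GreenhouseGas]

    def __post_init__(self) -> None:
        for table in (self.air, self.water, self.greenhouse):
            for name, f in table.items():
                if f.daly < 0 or f.pdf < 0:
                    raise ParameterError(f"impact factor {name!r} must be >= 0")


@dataclass(frozen=True)
class CognitionInputs:
    """Inputs of the per-capita health-expenditure emergy τ."""

    health_expenditure: float  # currency·yr⁻¹
    population: float  # capita
    emergy_money_ratio: float  # sej·currency⁻¹

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ParameterError("population must be > 0")
        if self.health_expenditure < 0:
            raise ParameterError("health_expenditure must be >= 0")
        if self.emergy_money_ratio < 0:
            raise ParameterError("emergy_money_ratio must be >= 0")


@dataclass
class RegionSpec:
    """Assignment of spatial units to precipitation zones."""

    zones: dict[str, str]

    def __post_init__(self) -> None:
        for unit, zone in self.zones.items():
            if zone not in ZONES:
                raise ParameterError(f"unknown zone {zone!r} for unit {unit!r}")

    def zone_of(self, unit_id: str) -> str:
        try:
            return self.zones[unit_id]
        except KeyError:
            raise ParameterError(f"unit {unit_id!r} has no zone assignment") from None


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------


def _params_to_dict(params: EmergyParams, factors: ImpactFactors) -> dict:
    return {
        "emergy": {
            "uev": dict(params.uev),
            "uev_minerals": dict(params.uev_minerals),
            "litter_biomass_ratio": dict(params.litter_biomass_ratio),
            "detritus_carbon_fraction": params.detritus_carbon_fraction,
            "g_to_kcal": dict(params.g_to_kcal),
            "mountain_density": params.mountain_density,
            "constants": dict(params.constants),
        },
        "impact": {
            "air": {
                n: {"uptake": dict(f.uptake), "daly": f.daly, "pdf": f.pdf}
                for n, f in factors.air.items()
            },
            "water": {
                n: {
                    "removal": dict(f.removal),
                    "daly": f.daly,
                    "pdf": f.pdf,
                    "turnover": f.turnover,
                }
                for n, f in factors.water.items()
            },
            "greenhouse": {
                n: {
                    "sequestration": dict(f.sequestration),
                    "daly": f.daly,
                    "pdf": f.pdf,
                    "lifetime": f.lifetime,
                }
                for n, f in factors.greenhouse.items()
            },
        },
    }


def save_params(path, params: EmergyParams, factors: ImpactFactors) -> None:
    """Serialize a parameter set to a YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(_params_to_dict(params, factors), fh, sort_keys=True)


def load_params(path) -> tuple[EmergyParams, ImpactFactors]:
    """Load and validate a parameter file.

    Defaults are applied only for the constants printed in the method text
    (runoff rate 0.25, mineral mass fraction 0.95, mineral turnover 1000 yr,
    aquatic absorption 0.78, deposition/NPP ratio 0.3037, kcal→J 4186,
    water density, gravity).  Everything else must be present.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterError("parameter file must be a mapping")
    try:
        em = doc["emergy"]
    except KeyError:
        raise ParameterError("missing key: 'emergy'") from None
    for key in ("uev", "uev_minerals", "litter_biomass_ratio",
                "detritus_carbon_fraction", "g_to_kcal", "mountain_density"):
        if key not in em:
            raise ParameterError(f"missing key: 'emergy.{key}'")
    params = EmergyParams(
        uev=dict(em["uev"]),
        uev_minerals=dict(em["uev_minerals"]),
        litter_biomass_ratio=dict(em["litter_biomass_ratio"]),
        detritus_carbon_fraction=float(em["detritus_carbon_fraction"]),
        g_to_kcal=dict(em["g_to_kcal"]),
        mountain_density=float(em["mountain_density"]),
        constants=dict(em.get("constants", {})),
    )
    try:
        imp = doc["impact"]
    except KeyError:
        raise ParameterError("missing key: 'impact'") from None
    factors = ImpactFactors(
        air={
            n: AirPollutant(uptake=dict(f["uptake"]), daly=float(f["daly"]),
                            pdf=float(f["pdf"]))
            for n, f in imp.get("air", {}).items()
        },
        water={
            n: WaterPollutant(removal=dict(f["removal"]), daly=float(f["daly"]),
                              pdf=float(f["pdf"]), turnover=float(f["turnover"]))
            for n, f in imp.get("water", {}).items()
        },
        greenhouse={
            n: GreenhouseGas(sequestration=dict(f["sequestration"]),
                             daly=float(f["daly"]), pdf=float(f["pdf"]),
                             lifetime=float(f["lifetime"]))
            for n, f in imp.get("greenhouse", {}).items()
        },
    )
    return params, factors


def demo_params() -> tuple[EmergyParams, ImpactFactors]:
    """A documented, NON-authoritative demo parameter set.

    Magnitudes are chosen so that service values land in the
    1e18–1e23 sej·yr⁻¹ range typical of national-scale emergy tables; the
    numbers carry no empirical authority.
    """
    all_classes = [c.value for c in EcosystemClass]
    aquatic = [c.value for c in EcosystemClass if c.is_aquatic]
    params = EmergyParams(
        uev={
            "uev_rain_chemical": 3.1e4,      # sej·g⁻¹
            "uev_rain_hydro": 3.1e4,         # sej·g⁻¹
            "uev_transpired_water": 6.6e4,   # sej·g⁻¹
            "uev_soil": 1.2e5,               # sej·J⁻¹
            "uev_mountain": 1.7e9,           # sej·g⁻¹
            "uev_runoff_geopotential": 4.7e4,  # sej·J⁻¹
            "uev_organic_sediment": 3.8e4,   # sej·J⁻¹
        },
        uev_minerals={"quartz": 5.0e7, "feldspar": 8.0e7, "mica": 1.1e8},
        litter_biomass_ratio={c: r for c, r in zip(
            all_classes, (0.05, 0.08, 0.12, 0.10, 0.08, 0.0, 0.0, 0.0, 0.0))},
        detritus_carbon_fraction=0.45,
        g_to_kcal={**{c: 4.5 for c in aquatic}, "soil": 4.0},
        mountain_density=2.6,
        constants={},
    )
    factors = ImpactFactors(
        air={
            name: AirPollutant(
                uptake={c: u for c in all_classes},
                daly=d, pdf=p)
            for name, u, d, p in (
                ("SO2", 88.0, 5.46e-5, 1.04e-4),
                ("fluoride", 4.6, 8.0e-5, 0.6e-4),
                ("NOx", 38.0, 8.87e-5, 5.71e-4),
                ("CO", 12.0, 7.3e-7, 0.2e-4),
                ("O3", 6.0, 3.9e-6, 0.3e-4),
                ("PM10", 21.0, 3.75e-4, 0.8e-4),
                ("PM2.5", 10.0, 7.0e-4, 1.2e-4),
            )
        },
        water={
            name: WaterPollutant(
                removal={c: m for c in aquatic},
                daly=d, pdf=p, turnover=t)
            for name, m, d, p, t in (
                ("Cr", 8.0, 3.43e-10, 9.73e-9, 40.0),
                ("Ni", 12.0, 2.0e-10, 5.0e-9, 40.0),
                ("Cu", 20.0, 1.0e-10, 8.5e-9, 35.0),
                ("Mn", 260.0, 5.0e-11, 1.2e-9, 50.0),
                ("Zn", 45.0, 8.0e-11, 2.2e-9, 30.0),
                ("Cd", 1.2, 1.2e-9, 2.0e-8, 55.0),
                ("Pb", 16.0, 6.0e-10, 1.2e-8, 60.0),
            )
        },
        greenhouse={
            name: GreenhouseGas(
                sequestration={c: s for c in all_classes},
                daly=d, pdf=p, lifetime=lt)
            for name, s, d, p, lt in (
                ("CO2", 0.48, 2.1e-7, 5.2e-3, 120.0),
                ("CH4", 0.004, 4.4e-6, 0.11, 12.0),
                ("NOx", 0.002, 6.2e-5, 1.5, 114.0),
                ("HFC", 1.0e-5, 3.0e-4, 7.5, 260.0),
            )
        },
    )
    return params, factors
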