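import pytest
from hypothesis import HealthCheck, settings

from emeserv.parameters import (
    AirPollutant,
    CognitionInputs,
    EcosystemClass,
    EmergyParams,
    GreenhouseGas,
    ImpactFactors,
    RenewableDrivers,
    SoilProfile,
    UnitRecord,
    WaterPollutant,
    demo_params,
)

settings.register_profile(
    "ci", deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_record(ecosystem=EcosystemClass.FOREST, *, unit_id="U0", epoch="t0",
                raw_area=1.0e6, **kw) -> UnitRecord:
    defaults = dict(
        ndvi=0.5, precipitation=1.0, evapotranspiration=5.0e5,
        elevation=100.0, npp=100.0, carbon_pool=500.0, carbon_turnover=50.0,
        infiltration_coeff=0.1,
        soil=SoilProfile(mineral_proportions={"quartz": 0.4}),
        renewable=RenewableDrivers(solar=1.0e12),
    )
    defaults.update(kw)
    return UnitRecord(unit_id=unit_id, ecosystem=ecosystem, epoch=epoch,
                      raw_area=raw_area, **defaults)


def unit_params(**overrides) -> EmergyParams:
    """Parameter set with every UEV = 1 so hand-derived chains are exact."""
    base = dict(
        uev={k: 1.0 for k in (
            "uev_rain_chemical", "uev_rain_hydro", "uev_transpired_water",
            "uev_soil", "uev_mountain", "uev_runoff_geopotential",
            "uev_organic_sediment")},
        uev_minerals={"quartz": 1.0},
        litter_biomass_ratio={c.value: 0.05 for c in EcosystemClass},
        detritus_carbon_fraction=0.5,
        g_to_kcal={**{c.value: 4.0 for c in EcosystemClass if c.is_aquatic},
                   "soil": 4.0},
        mountain_density=1.0,
        constants={},
    )
    base.update(overrides)
    return EmergyParams(**base)


def single_air_factors(uptake=10.0, daly=1.0e-3, pdf=0.0) -> ImpactFactors:
    return ImpactFactors(
        air={"SO2": AirPollutant(
            uptake={c.value: uptake for c in EcosystemClass},
            daly=daly, pdf=pdf)},
        water={}, greenhouse={})


@pytest.fixture
def params():
    return unit_params()


@pytest.fixture
def demo():
    return demo_params()


@pytest.fixture
def cognition():
    # tau = 1e9 * 1e12 / 1e6 = 1e15 sej/cap
    return CognitionInputs(health_expenditure=1.0e9, population=1.0e6,
                           emergy_money_ratio=1.0e12)


def empty_factors() -> ImpactFactors:
    return ImpactFactors(air={}, water={}, greenhouse={})


def water_factor(removal, daly, pdf, turnover) -> ImpactFactors:
    return ImpactFactors(
        air={},
        water={"Cr": WaterPollutant(
            removal={c.value: removal for c in EcosystemClass if c.is_aquatic},
            daly=daly, pdf=pdf, turnover=turnover)},
        greenhouse={})


def gas_factor(seq, daly, pdf, lifetime) -> ImpactFactors:
    return ImpactFactors(
        air={}, water={},
        greenhouse={"CO2": GreenhouseGas(
            sequestration={c.value: seq for c in EcosystemClass},
            daly=daly, pdf=pdf, lifetime=lifetime)})
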