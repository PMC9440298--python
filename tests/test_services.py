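import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from emeserv import services as svc
from emeserv.parameters import (
    CognitionInputs,
    EcosystemClass,
    ParameterError,
    RenewableDrivers,
    SoilProfile,
)
from emeserv.services import (
    SERVICE_APPLICABILITY,
    ApplicabilityError,
    account_record,
    air_purification,
    carbon_sequestration,
    climate_regulation,
    groundwater_recharge,
    hydropower_potential,
    materials_transport,
    microclimate_regulation,
    sediment_building,
    soil_building,
    soil_retention,
    tau_h,
    water_purification,
)
from emeserv.parameters import DamRecord

from conftest import (
    empty_factors,
    gas_factor,
    make_record,
    single_air_factors,
    unit_params,
    water_factor,
)


class TestTauH:
    def test_example(self):
        assert tau_h(CognitionInputs(1e9, 1e6, 1e12)) == 1e15

    def test_zero_expenditure(self):
        assert tau_h(CognitionInputs(0.0, 1e6, 1e12)) == 0.0

    def test_homogeneity(self):
        a = tau_h(CognitionInputs(1e9, 1e6, 1e12))
        b = tau_h(CognitionInputs(2e9, 2e6, 1e12))
        assert a == b


class TestCarbonSequestration:
    def test_uev_derivation_and_value(self):
        r = make_record(npp=100.0, carbon_pool=500.0, carbon_turnover=50.0)
        res = carbon_sequestration(r, corrected_area=1e4, em_npp=1e12)
        assert res.meta["uev_cs"] == pytest.approx(1e6)
        assert res.value == pytest.approx(1e11)

    def test_cross_form_identity(self):
        r = make_record(npp=137.0, carbon_pool=812.0, carbon_turnover=31.0)
        em_npp = 7.3e19
        res = carbon_sequestration(r, corrected_area=5.5e8, em_npp=em_npp)
        alt = em_npp * r.carbon_pool / (r.carbon_turnover * r.npp)
        assert res.value == pytest.approx(alt, rel=1e-12)

    def test_zero_pool(self):
        r = make_record(carbon_pool=0.0)
        assert carbon_sequestration(r, 1e4, 1e12).value == 0.0

    def test_zero_npp_error(self):
        r = make_record(npp=0.0, carbon_pool=10.0)
        with pytest.raises(ParameterError):
            carbon_sequestration(r, 1e4, 1e12)


class TestSoilBuilding:
    def test_organic_term(self):
        params = unit_params(
            litter_biomass_ratio={c.value: 0.05 for c in EcosystemClass},
            detritus_carbon_fraction=0.5)
        r = make_record(soil=SoilProfile(mineral_proportions={}))
        res = soil_building(r, 1e4, 1e12, params)
        assert res.components["organic"] == pytest.approx(2.5e10)
        assert res.components["mineral"] == 0.0

    def test_mineral_max(self):
        # two species; terms computed by the published chain with UEV=1
        params = unit_params(uev_minerals={"a": 1.0, "b": 1.0})
        soil = SoilProfile(bulk_density=1.0, depth=1.0,
                           mineral_proportions={"a": 0.4, "b": 0.7})
        r = make_record(soil=soil)
        res = soil_building(r, 1e4, 0.0, params)
        c = params.constants
        def term(pm):
            return (pm * 1.0 * 1.0 * 1e4 * c["mineral_mass_fraction"]
                    * c["m2_to_cm2"] / c["mineral_turnover"])
        assert res.components["mineral"] == pytest.approx(term(0.7))
        assert res.meta["winning_mineral"] == "b"

    def test_zero_everything(self):
        params = unit_params(
            litter_biomass_ratio={c.value: 0.0 for c in EcosystemClass})
        r = make_record(soil=SoilProfile(mineral_proportions={"quartz": 0.0}))
        assert soil_building(r, 1e4, 1e12, params).value == 0.0

    def test_aquatic_rejected(self, params):
        r = make_record(EcosystemClass.LAKE)
        with pytest.raises(ApplicabilityError):
            soil_building(r, 1e4, 1e12, params)


class TestSedimentBuilding:
    def test_om_ratio(self, params):
        r = make_record(EcosystemClass.LAKE, npp=100.0)
        res = sediment_building(r, 1.0, params)
        assert res.meta["om_deposition"] == pytest.approx(30.37)

    def test_chain_product(self, params):
        r = make_record(EcosystemClass.LAKE, npp=100.0)
        res = sediment_building(r, 1.0, params)
        expected = 30.37 * 0.78 * 4.0 * 4186.0 * 1.0 * 1.0
        assert res.value == pytest.approx(expected)
        assert expected == pytest.approx(3.966e5, rel=1e-3)

    def test_eutrophic_absent(self, params):
        r = make_record(EcosystemClass.LAKE, eutrophic=True)
        assert sediment_building(r, 1.0, params) is None

    def test_terrestrial_rejected(self, params):
        with pytest.raises(ApplicabilityError):
            sediment_building(make_record(), 1.0, params)


class TestGroundwaterRecharge:
    def test_example(self, params):
        r = make_record(precipitation=1.0, infiltration_coeff=0.1)
        assert groundwater_recharge(r, 1.0, params).value == pytest.approx(1e5)

    def test_zero_infiltration(self, params):
        r = make_record(infiltration_coeff=0.0)
        assert groundwater_recharge(r, 1.0, params).value == 0.0

    def test_linear_in_area(self, params):
        r = make_record(precipitation=1.0, infiltration_coeff=0.1)
        a = groundwater_recharge(r, 1.0, params).value
        b = groundwater_recharge(r, 2.0, params).value
        assert b == pytest.approx(2 * a)


class TestAirPurification:
    def test_single_pollutant_hh(self, params):
        factors = single_air_factors(uptake=10.0, daly=1e-3, pdf=0.0)
        r = make_record()
        res = air_purification(r, 1e4, factors, tau=1e15, em_sp=0.0,
                               params=params)
        assert res.components["HH"] == pytest.approx(1e13)

    def test_all_zero(self, params):
        factors = single_air_factors(uptake=0.0)
        res = air_purification(make_record(), 1e4, factors, 1e15, 1e20, params)
        assert res.value == 0.0

    def test_additive_over_pollutants(self, params):
        from emeserv.parameters import AirPollutant, ImpactFactors
        one = single_air_factors(uptake=10.0, daly=1e-3)
        h1 = air_purification(make_record(), 1e4, one, 1e15, 0.0,
                              params).components["HH"]
        two = ImpactFactors(air={
            "SO2": one.air["SO2"],
            "NOx": AirPollutant(uptake={c.value: 10.0 for c in EcosystemClass},
                                daly=1e-3, pdf=0.0)},
            water={}, greenhouse={})
        h2 = air_purification(make_record(), 1e4, two, 1e15, 0.0,
                              params).components["HH"]
        assert h2 == pytest.approx(2 * h1)

    def test_eq_uses_max_renewable(self, params):
        factors = single_air_factors(uptake=2.0, daly=0.0, pdf=0.5)
        res = air_purification(make_record(), 1e4, factors, 0.0, 1e20, params)
        assert res.components["EQ"] == pytest.approx(2.0 * 0.5 * 1e20)


class TestWaterPurification:
    def test_single_metal_hh(self, params):
        # M·NPP·S'·DALY·τ = 1e10 with T = 10 -> HH = 1e9
        factors = water_factor(removal=1.0, daly=1.0, pdf=0.0, turnover=10.0)
        r = make_record(EcosystemClass.LAKE, npp=100.0)
        res = water_purification(r, 1e4, factors, tau=1e4, em_sp=0.0,
                                 params=params)
        assert res.components["HH"] == pytest.approx(1e9)

    def test_zero_removal(self, params):
        factors = water_factor(0.0, 1.0, 1.0, 10.0)
        r = make_record(EcosystemClass.LAKE)
        assert water_purification(r, 1e4, factors, 1e15, 1e20,
                                  params).value == 0.0

    def test_inverse_turnover(self, params):
        r = make_record(EcosystemClass.LAKE, npp=100.0)
        a = water_purification(r, 1e4, water_factor(1.0, 1.0, 0.0, 10.0),
                               1e4, 0.0, params).value
        b = water_purification(r, 1e4, water_factor(1.0, 1.0, 0.0, 5.0),
                               1e4, 0.0, params).value
        assert b == pytest.approx(2 * a)

    def test_terrestrial_rejected(self, params):
        with pytest.raises(ApplicabilityError):
            water_purification(make_record(), 1e4, empty_factors(), 1e15,
                               1e20, params)


class TestSoilRetention:
    def test_chain_product(self):
        params = unit_params()
        soil = SoilProfile(retention_amount=2.0, som_fraction=0.02,
                           mineral_proportions={})
        r = make_record(soil=soil)
        res = soil_retention(r, 1e4, params)  # 1e4 m² = 1 ha
        assert res.value == pytest.approx(2 * 1 * 0.02 * 1e6 * 4.0 * 4186.0)
        assert res.value == pytest.approx(6.6976e8)

    def test_zero_retention(self, params):
        soil = SoilProfile(retention_amount=0.0, mineral_proportions={})
        assert soil_retention(make_record(soil=soil), 1e4, params).value == 0.0

    def test_aquatic_rejected(self, params):
        with pytest.raises(ApplicabilityError):
            soil_retention(make_record(EcosystemClass.RIVER), 1e4, params)


class TestMicroclimateRegulation:
    def test_example(self):
        params = unit_params()
        params.uev["uev_transpired_water"] = 1e3
        r = make_record(evapotranspiration=5e5)
        assert microclimate_regulation(r, 1e4, params).value == \
            pytest.approx(5e12)

    def test_zero_et(self, params):
        assert microclimate_regulation(make_record(evapotranspiration=0.0),
                                       1e4, params).value == 0.0

    def test_uev_scaling(self, params):
        r = make_record(evapotranspiration=5e5)
        a = microclimate_regulation(r, 1e4, params).value
        params.uev["uev_transpired_water"] *= 2
        assert microclimate_regulation(r, 1e4, params).value == \
            pytest.approx(2 * a)


class TestMaterialsTransport:
    def test_chain_product(self, params):
        r = make_record(EcosystemClass.RIVER, precipitation=1.0,
                        elevation=100.0)
        res = materials_transport(r, 1.0, params)
        assert res.value == pytest.approx(1 * 1 * 1000 * 0.25 * 100 * 9.8 * 1)
        assert res.value == pytest.approx(2.45e5)

    def test_zero_elevation(self, params):
        r = make_record(EcosystemClass.RIVER, elevation=0.0)
        assert materials_transport(r, 1.0, params).value == 0.0

    def test_default_runoff_rate(self, params):
        assert params.constants["runoff_rate"] == 0.25

    def test_non_river_rejected(self, params):
        with pytest.raises(ApplicabilityError):
            materials_transport(make_record(EcosystemClass.LAKE), 1.0, params)


class TestHydropower:
    def test_rain_term(self):
        params = unit_params()
        params.constants["hg_mass_conversion"] = 1.0  # declared mass units
        dam = DamRecord(1e6, 1.0, 0.0, 0.5)
        r = make_record(EcosystemClass.RIVER, dams=[dam])
        res = hydropower_potential(r, params)
        assert res.components["rain"] == pytest.approx(1e9)

    def test_no_dams(self, params):
        r = make_record(EcosystemClass.RIVER)
        assert hydropower_potential(r, params).value == 0.0

    def test_two_identical_dams_double(self, params):
        dam = DamRecord(1e6, 1.0, 1e-4, 0.5)
        r1 = make_record(EcosystemClass.RIVER, dams=[dam])
        r2 = make_record(EcosystemClass.RIVER, dams=[dam, dam])
        assert hydropower_potential(r2, params).value == \
            pytest.approx(2 * hydropower_potential(r1, params).value)

    def test_mountain_term(self):
        params = unit_params(mountain_density=2.0)
        dam = DamRecord(1e6, 0.0, 1e-4, 0.5)
        r = make_record(EcosystemClass.RIVER, dams=[dam])
        res = hydropower_potential(r, params)
        assert res.components["mountain"] == \
            pytest.approx(1e6 * 1e-4 * 1e6 * 2.0 * 1.0)


class TestClimateRegulation:
    def test_hh_division_by_lifetime(self):
        # C·DALY·S'·τ = 1e12 with LT = 100 -> HH = 1e10
        factors = gas_factor(seq=1.0, daly=1.0, pdf=0.0, lifetime=100.0)
        r = make_record()
        res = climate_regulation(r, 1e4, factors, tau=1e8, em_sp=0.0)
        assert res.components["HH"] == pytest.approx(1e10)

    def test_zero_sequestration(self):
        factors = gas_factor(0.0, 1.0, 1.0, 100.0)
        assert climate_regulation(make_record(), 1e4, factors, 1e15,
                                  1e20).value == 0.0

    def test_inverse_lifetime(self):
        r = make_record()
        a = climate_regulation(r, 1e4, gas_factor(1.0, 1.0, 1.0, 100.0),
                               1e8, 1e10).value
        b = climate_regulation(r, 1e4, gas_factor(1.0, 1.0, 1.0, 200.0),
                               1e8, 1e10).value
        assert a == pytest.approx(2 * b)


class TestApplicabilityMatrix:
    def test_matrix_shape(self):
        for eco, services_ in SERVICE_APPLICABILITY.items():
            if eco.is_terrestrial:
                assert set(services_) == {"NPP", "CS", "SB", "GR", "AP", "SR",
                                          "MR", "CR"}
            elif eco.is_river:
                assert set(services_) == {"NPP", "CS", "SBa", "GR", "AP", "WP",
                                          "MR", "CR", "MT", "HG"}
            else:
                assert set(services_) == {"NPP", "CS", "SBa", "GR", "AP", "WP",
                                          "MR", "CR"}

    @pytest.mark.parametrize("eco", list(EcosystemClass))
    def test_account_record_respects_matrix(self, eco, params, cognition):
        r = make_record(eco)
        led = account_record(r, 1e4, 0.5, params, empty_factors(), cognition)
        produced = set(led.services)
        allowed = set(SERVICE_APPLICABILITY[eco])
        assert produced <= allowed
        assert {"NPP", "CS", "GR", "AP", "MR", "CR"} <= produced


class TestHomogeneityInArea:
    area_dependent = ("CS", "SB", "SBa", "GR", "AP", "SR", "MR", "WP", "MT")

    @pytest.mark.parametrize("eco", [EcosystemClass.FOREST,
                                     EcosystemClass.LAKE,
                                     EcosystemClass.RIVER])
    @given(c=st.floats(0.1, 10.0))
    def test_degree_one(self, eco, c, ):
        params = unit_params()
        r = make_record(eco)
        funcs = {
            "CS": lambda a: carbon_sequestration(r, a, 1e12 * a).value,
            "GR": lambda a: groundwater_recharge(r, a, params).value,
            "MR": lambda a: microclimate_regulation(r, a, params).value,
        }
        if eco.is_terrestrial:
            funcs["SB"] = lambda a: soil_building(r, a, 1e12 * a, params).value
            funcs["SR"] = lambda a: soil_retention(r, a, params).value
        else:
            funcs["SBa"] = lambda a: sediment_building(r, a, params).value
        if eco.is_river:
            funcs["MT"] = lambda a: materials_transport(r, a, params).value
        for name, f in funcs.items():
            base = f(1e4)
            assert f(1e4 * c) == pytest.approx(base * c, rel=1e-9), name

    @given(c=st.floats(0.1, 10.0))
    def test_hydropower_homogeneous_in_catchment(self, c):
        params = unit_params()
        dam = DamRecord(1e6, 1.0, 1e-4, 0.5)
        scaled = DamRecord(1e6 * c, 1.0, 1e-4, 0.5)
        v1 = hydropower_potential(
            make_record(EcosystemClass.RIVER, dams=[dam]), params).value
        v2 = hydropower_potential(
            make_record(EcosystemClass.RIVER, dams=[scaled]), params).value
        assert v2 == pytest.approx(v1 * c, rel=1e-9)


def test_all_outputs_nonnegative(params, cognition):
    from emeserv.parameters import demo_params
    dparams, dfactors = demo_params()
    for eco in EcosystemClass:
        led = account_record(make_record(eco), 1e6, 0.5, dparams, dfactors,
                             cognition)
        for name, sv in led.services.items():
            assert sv.value >= 0.0, (eco, name)
            for comp, v in sv.components.items():
                assert v >= 0.0, (eco, name, comp)
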