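"""Seeded two-epoch fixture generation with controlled driver deltas.

Fixtures are fully deterministic in the seed.  Planned deltas are applied
multiplicatively between epochs; jitter perturbs the *baseline* draw only,
identically in both epochs, so a plan's deltas are exactly recoverable
whenever jitter does not interact with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import (
    ZONES,
    CognitionInputs,
    DamRecord,
    EcosystemClass,
    EmergyParams,
    ImpactFactors,
    ParameterError,
    RegionSpec,
    RenewableDrivers,
    SoilProfile,
    UnitRecord,
    demo_params,
)

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "worked_example",
           "default_plan"]


def default_plan() -> dict[str, dict[str, float]]:
    """A mixed two-epoch change plan for demo workspaces: growing forests
    and grasslands, shrinking shrub, wetter south-style aquatic classes."""
    return {
        "F1": {"area": 0.20, "evapotranspiration": 0.08},
        "F2": {"area": -0.05, "evapotranspiration": 0.04},
        "G1": {"area": 0.10, "precipitation": -0.05},
        "G2": {"area": 0.08, "precipitation": -0.03},
        "G3": {"area": 0.05},
        "A1": {"area": 0.04, "precipitation": 0.05},
        "A2": {"area": -0.02, "npp": 0.05},
        "A3": {"area": 0.12},
        "A4": {"area": 0.06, "precipitation": 0.05},
    }

#: delta-plan knobs understood by the generator
DELTA_KEYS = ("area", "ndvi", "precipitation", "evapotranspiration", "npp",
              "tau")


@dataclass
class FixtureSpec:
    seed: int = 0
    n_units: int = 4
    classes: tuple[EcosystemClass, ...] = tuple(EcosystemClass)
    deltas: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: applied to the per-extent cognition inputs between epochs
    tau_delta: float = 0.0
    jitter: float = 0.0
    region_layout: Mapping[str, float] = field(
        default_factory=lambda: {ZONES[0]: 0.25, ZONES[1]: 0.25, ZONES[2]: 0.5})
    epochs: tuple[str, str] = ("t0", "t1")

    def __post_init__(self) -> None:
        for cls, plan in self.deltas.items():
            for key, d in plan.items():
                if key not in DELTA_KEYS:
                    raise ParameterError(f"unknown delta knob {key!r}")
                if d <= -1.0:
                    raise ParameterError(
                        f"delta {key!r} for {cls!r} must be > -1, got {d}")
        if self.tau_delta <= -1.0:
            raise ParameterError("tau_delta must be > -1")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")


@dataclass
class Fixture:
    records: dict[str, list[UnitRecord]]  # epoch -> records
    regions: RegionSpec
    cognition: dict[str, CognitionInputs]  # epoch -> inputs
    params: EmergyParams
    factors: ImpactFactors


def _plan(spec: FixtureSpec, eco: EcosystemClass, key: str) -> float:
    return spec.deltas.get(eco.value, {}).get(key, 0.0)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Materialize a deterministic two-epoch record set from a plan."""
    rng = np.random.default_rng(spec.seed)
    params, factors = demo_params()
    e0, e1 = spec.epochs

    def jit() -> float:
        if spec.jitter == 0.0:
            # burn a draw so record geometry is stable across jitter settings
            rng.normal()
            return 1.0
        return float(np.exp(rng.normal(0.0, spec.jitter)))

    records: dict[str, list[UnitRecord]] = {e0: [], e1: []}
    for u in range(spec.n_units):
        unit_id = f"U{u:03d}"
        for eco in spec.classes:
            area0 = float(rng.uniform(1e8, 5e9)) * jit()  # m²
            ndvi0 = float(rng.uniform(0.3, 0.8))
            precip0 = float(rng.uniform(0.3, 1.6)) * jit()  # m/yr
            et0 = float(rng.uniform(2e5, 8e5)) * jit()  # g/m²/yr
            npp0 = float(rng.uniform(150.0, 900.0)) * jit()  # gC/m²/yr
            elev = float(rng.uniform(50.0, 2500.0))
            carbon0 = npp0 * float(rng.uniform(8.0, 25.0))
            turnover = float(rng.uniform(15.0, 60.0))
            infil = float(rng.uniform(0.05, 0.35))

            # per-area renewable intensities (sej·m⁻²·yr⁻¹); extensive flows
            # scale with raw area so pure-area plans keep intensities fixed
            base = {
                "solar": float(rng.uniform(1e9, 4e9)),
                "tidal": 0.0,
                "geothermal": float(rng.uniform(1e8, 5e8)),
                "wave": 0.0,
                "wind": float(rng.uniform(5e8, 3e9)),
            }
            rain_i = 3.0e9 * precip0
            rgeo_i = 1.5e9 * precip0 * (elev / 1000.0)
            rchem_i = 1.0e9 * precip0

            soil = SoilProfile(
                bulk_density=float(rng.uniform(1.1, 1.6)),
                depth=float(rng.uniform(10.0, 40.0)),
                mineral_proportions={"quartz": 0.4, "feldspar": 0.3,
                                     "mica": 0.1},
                som_fraction=float(rng.uniform(0.01, 0.05)),
                retention_amount=float(rng.uniform(0.5, 4.0)),
            )
            dams = []
            if eco.is_river:
                dams = [DamRecord(
                    catchment_area=area0 * 0.4,
                    rainfall=precip0,
                    deviation_rate=1.5e-5,
                    position_x=float(rng.uniform(0.1, 0.9)))]

            for epoch, grow in ((e0, False), (e1, True)):
                def scale(key: str, v: float) -> float:
                    return v * (1.0 + _plan(spec, eco, key)) if grow else v

                area = scale("area", area0)
                precip = scale("precipitation", precip0)
                af = area / area0 if area0 > 0 else 0.0
                pf = precip / precip0 if precip0 > 0 else 0.0
                renew = RenewableDrivers(
                    solar=base["solar"] * area,
                    tidal=base["tidal"] * area,
                    geothermal=base["geothermal"] * area,
                    wave=base["wave"] * area,
                    wind=base["wind"] * area,
                    rain_chemical=rain_i * pf * area,
                    runoff_geopotential=rgeo_i * pf * area,
                    runoff_chemical=rchem_i * pf * area,
                )
                eco_dams = dams
                if eco.is_river and grow:
                    eco_dams = [DamRecord(d.catchment_area * af * pf,
                                          d.rainfall * pf, d.deviation_rate,
                                          d.position_x) for d in dams]
                records[epoch].append(UnitRecord(
                    unit_id=unit_id, ecosystem=eco, epoch=epoch,
                    raw_area=area,
                    ndvi=min(1.0, scale("ndvi", ndvi0)),
                    precipitation=precip,
                    evapotranspiration=scale("evapotranspiration", et0),
                    elevation=elev,
                    npp=scale("npp", npp0),
                    carbon_pool=scale("npp", carbon0),
                    carbon_turnover=turnover,
                    infiltration_coeff=infil,
                    soil=soil,
                    eutrophic=False,
                    renewable=renew,
                    dams=eco_dams,
                ))

    # round-robin region assignment by the layout fractions
    fracs = [spec.region_layout.get(z, 0.0) for z in ZONES]
    total = sum(fracs) or 1.0
    bounds = np.cumsum([f / total for f in fracs])
    zones = {}
    for u in range(spec.n_units):
        q = (u + 0.5) / spec.n_units
        zone = ZONES[min(int(np.searchsorted(bounds, q)), len(ZONES) - 1)]
        zones[f"U{u:03d}"] = zone
    regions = RegionSpec(zones=zones)

    cog0 = CognitionInputs(health_expenditure=5.0e12, population=1.0e8,
                           emergy_money_ratio=5.0e10)
    cog1 = CognitionInputs(
        health_expenditure=cog0.health_expenditure * (1.0 + spec.tau_delta),
        population=cog0.population,
        emergy_money_ratio=cog0.emergy_money_ratio)
    return Fixture(records=records, regions=regions,
                   cognition={e0: cog0, e1: cog1},
                   params=params, factors=factors)


def worked_example() -> dict:
    """The tiny in-repo example set used by the operation-level tests.

    Contains (a) the bilinear decomposition toy with its hand-computed
    residual, (b) the additive river-total case, and (c) a published-style
    three-region contribution table with its expected integer-percent
    renderings.
    """
    return {
        "bilinear": {
            # Y = E·S + S·τ
            "state0": {"R": 2.0, "tau": 1.0, "S": 10.0},
            "state1": {"R": 3.0, "tau": 1.0, "S": 12.0},
            "expected": {"Cr_R": 10.0, "Cr_tau": 0.0, "Cr_S": 6.0,
                         "delta": 2.0, "dY": 18.0},
        },
        "river_case_b": {
            "five_group": {"NPP": 5e20, "CS": 3e20, "SBa": 2e20, "GR": 1e20,
                           "MR": 4e20},
            "WP": 1e20, "AP": 1e20, "HG": 2e20, "CR": 1e20,
            "expected_total": 10e20,
        },
        "regional_contributions": {
            "north_of_400mm": {"R": 1.26e22, "tau": 6.63e21, "S": 4.59e22,
                               "delta": -8.16e20, "subtotal": 6.43e22},
            "between_400_800mm": {"R": -2.94e20, "tau": 2.74e21, "S": 2.66e22,
                                  "delta": 6.41e19, "subtotal": 2.91e22},
            "south_of_800mm": {"R": 6.12e22, "tau": 6.68e21, "S": 3.65e22,
                               "delta": 1.93e21, "subtotal": 1.06e23},
        },
        "regional_per_eco_area_intensity": {
            "north_of_400mm": 5.00e10,
            "between_400_800mm": 4.31e10,
            "south_of_800mm": 1.07e11,
        },
        "expected_rate_pct": {
            "north_of_400mm": {"R": 20, "tau": 10, "S": 71, "delta": -1},
            "between_400_800mm": {"R": -1, "tau": 9, "S": 91, "delta": 0},
            "south_of_800mm": {"R": 58, "tau": 6, "S": 34, "delta": 2},
        },
        "expected_ratio_pct": {"north_of_400mm": 32, "south_of_800mm": 53},
    }
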