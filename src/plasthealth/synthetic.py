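"""Synthetic world generator.

Real runs of this pipeline need two external inputs: a deposited
material-flow dataset (annual Mt per scenario/archetype/category/stage with
Monte Carlo replicates) and unit impact factors derived from a licensed
inventory database.  This module generates structurally faithful synthetic
stand-ins for both with known ground truth, so every pipeline stage is
testable offline:

* polymer-level process inventories per lifecycle stage, with an aggregate
  grid-electricity input for regionalization and literature-plausible
  (explicitly illustrative) emission intensities;
* archetype electricity mixes whose fossil share falls with income rank;
* an illustrative characterization table (ReCiPe-2016-style endpoint
  factors; GWP100 for fossil methane is 29.8 kg CO2-eq/kg per IPCC AR6);
* mass-balanced six-scenario flow trajectories 2016-2040 with seeded
  lognormal replicate perturbations applied at the production source node
  and propagated through fixed routing shares (so every replicate is
  mass-conserving at every node);
* ground-truth unit factors computed by direct supply-chain expansion —
  an independent oracle for the matrix-based inventory solver.

The generated networks are acyclic with depth <= 3 (stage process ->
electricity technology / combustion -> fuel supply), which keeps the
expansion oracle exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import (
    CategoryComposition,
    FactorTable,
    PolymerProfile,
    ReuseSystemSpec,
    UnitImpactFactor,
    compose_category_inventory,
    compute_unit_factor,
    reuse_system_factor,
)
from .characterization import CharacterizationTable, characterize, total_dalys
from .constants import (
    ARCHETYPES,
    CATEGORIES,
    MIDPOINTS,
    REUSE_SYSTEMS,
    SCENARIOS,
    SINGLE_USE_SUBSTITUTES,
    STAGES,
    ZERO_EFFECT_STAGES,
)
from .coupling import (
    POINT_REPLICATE,
    SAME_MATERIAL,
    CreditRule,
    SubstitutionSpec,
)
from .exceptions import SchemaError
from .inventory import ElectricityMix, ProcessInventory, regionalize_electricity

__all__ = [
    "ScenarioLevers",
    "WorldConfig",
    "SyntheticWorld",
    "gen_world",
    "gen_flows",
    "gen_replicates",
    "gen_reference_config",
    "check_conservation",
    "SAME_MATERIAL",
]

POLYMERS = ("pet", "hdpe", "ldpe", "pp", "ps", "pvc")

_MT = 1.0e9  # kg per Mt


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioLevers:
    """Per-scenario intervention strengths, ramped linearly over time.

    Each lever is its full-strength value, reached at ``ramp_end``; levers
    ramp linearly from zero at ``ramp_start``.  ``production_cut`` is the
    fraction of baseline demand removed; ``substitution_share`` is the part
    of that cut met by substitutes (the rest is outright elimination);
    ``collection_boost`` adds to the baseline collection share (capped);
    ``recycling_boost`` shifts sorted mass into recycling routes;
    ``incineration_boost`` shifts sorted mass into incineration.
    """

    production_cut: float = 0.0
    substitution_share: float = 0.0
    collection_boost: float = 0.0
    recycling_boost: float = 0.0
    incineration_boost: float = 0.0
    ramp_start: int = 2020
    ramp_end: int = 2040
    # market-penetration lags: per-lever ramp windows override the default
    collection_ramp: tuple[int, int] | None = None
    recycling_ramp: tuple[int, int] | None = None

    @staticmethod
    def _ramp(year: int, start: int, end: int) -> float:
        if year <= start:
            return 0.0
        if year >= end:
            return 1.0
        return (year - start) / (end - start)

    def ramp(self, year: int) -> float:
        return self._ramp(year, self.ramp_start, self.ramp_end)

    def ramp_collection(self, year: int) -> float:
        start, end = self.collection_ramp or (self.ramp_start, self.ramp_end)
        return self._ramp(year, start, end)

    def ramp_recycling(self, year: int) -> float:
        start, end = self.recycling_ramp or (self.ramp_start, self.ramp_end)
        return self._ramp(year, start, end)


def _default_levers() -> dict[str, ScenarioLevers]:
    return {
        "bau": ScenarioLevers(),
        "current_commitments": ScenarioLevers(
            production_cut=0.06,
            substitution_share=0.30,
            collection_boost=0.08,
            recycling_boost=0.03,
        ),
        "collect_dispose": ScenarioLevers(
            collection_boost=0.40, incineration_boost=0.18
        ),
        "recycling": ScenarioLevers(
            collection_boost=0.22, recycling_boost=0.32
        ),
        "reduce_substitute": ScenarioLevers(
            production_cut=0.52, substitution_share=0.50, collection_boost=0.05
        ),
        # collection expansion lags behind demand reduction (infrastructure
        # build-out), hence the later collection ramp window
        "system_change": ScenarioLevers(
            production_cut=0.52,
            substitution_share=0.50,
            collection_boost=0.40,
            collection_ramp=(2030, 2040),
            recycling_boost=0.32,
            incineration_boost=0.10,
        ),
    }


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the synthetic world.

    Defaults emulate the modelled global system: 2016-2040 window, six
    scenarios, eight archetypes, three plastics categories, ~3.2%/yr
    baseline demand growth, 300 Monte Carlo flow replicates with a modest
    lognormal dispersion (the flow dataset's reported intervals are a few
    percent wide).
    """

    seed: int = 0
    years: tuple[int, int] = (2016, 2040)
    n_replicates: int = 300
    dispersion: float = 0.04
    bau_growth: float = 0.032
    demand_2016_mt: float = 220.0
    levers: dict[str, ScenarioLevers] = field(default_factory=_default_levers)
    emission_scale: float = 1.0  # global multiplier on emission intensities

    def __post_init__(self) -> None:
        lo, hi = self.years
        if hi < lo:
            raise SchemaError(f"invalid year window {self.years}")
        if self.dispersion < 0 or not np.isfinite(self.bau_growth):
            raise SchemaError("dispersion must be >= 0 and growth finite")
        missing = set(SCENARIOS) - set(self.levers)
        if missing:
            raise SchemaError(f"levers missing for scenarios: {sorted(missing)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levers"] = {k: dataclasses.asdict(v) for k, v in self.levers.items()}
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        d = dict(d)
        if "levers" in d:
            def _lever(v: dict) -> ScenarioLevers:
                v = {
                    k: tuple(x) if k.endswith("_ramp") and x is not None else x
                    for k, x in v.items()
                }
                return ScenarioLevers(**v)

            d["levers"] = {k: _lever(v) for k, v in d["levers"].items()}
        if "years" in d:
            d["years"] = tuple(d["years"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Archetype parameters (baseline routing and electricity)
# ---------------------------------------------------------------------------

# share of global demand / collection share / informal share of collected /
# baseline incineration share of sorted
_ARCH_PARAMS: dict[str, dict[str, float]] = {
    "hi_urban": dict(demand=0.22, collect=0.97, informal=0.02, incin=0.36),
    "hi_rural": dict(demand=0.05, collect=0.90, informal=0.03, incin=0.30),
    "umi_urban": dict(demand=0.20, collect=0.85, informal=0.10, incin=0.22),
    "umi_rural": dict(demand=0.08, collect=0.72, informal=0.12, incin=0.16),
    "lmi_urban": dict(demand=0.18, collect=0.62, informal=0.25, incin=0.10),
    "lmi_rural": dict(demand=0.10, collect=0.45, informal=0.28, incin=0.06),
    "li_urban": dict(demand=0.10, collect=0.42, informal=0.38, incin=0.04),
    "li_rural": dict(demand=0.07, collect=0.30, informal=0.40, incin=0.03),
}

_CATEGORY_SHARES = {"rigid_mono": 0.45, "flexible_mono": 0.38, "multilayer_multi": 0.17}

# baseline sorted-mass routing (remainder to engineered landfill)
_BASE_ROUTES = dict(mech_closed=0.05, mech_open=0.05, chemical=0.01)
# uncollected-mass routing
_UNCOLLECTED = dict(open_burning=0.55, dumpsite=0.30, littering=0.15)
_LITTER_SPLIT = dict(aquatic=0.35, terrestrial=0.65)
_CLEANUP_SHARE = 0.12  # of aquatic litter recovered by organized clean-ups

# fossil share of grid electricity falls with income rank (worst health
# effects per kWh in lower-income archetypes)
_FOSSIL_SHARE = {
    "hi_urban": 0.42, "hi_rural": 0.46,
    "umi_urban": 0.60, "umi_rural": 0.64,
    "lmi_urban": 0.76, "lmi_rural": 0.80,
    "li_urban": 0.70, "li_rural": 0.74,
}

# household washing split (hand, dishwasher) by archetype
_WASH_SHARES = {
    "hi_urban": (0.35, 0.65), "hi_rural": (0.45, 0.55),
    "umi_urban": (0.55, 0.45), "umi_rural": (0.65, 0.35),
    "lmi_urban": (0.80, 0.20), "lmi_rural": (0.88, 0.12),
    "li_urban": (0.95, 0.05), "li_rural": (0.98, 0.02),
}


def electricity_mix(archetype_id: str, fossil_share: float | None = None) -> ElectricityMix:
    """Archetype grid mix: fossil split coal/gas/oil, rest nuclear/renewables."""
    f = _FOSSIL_SHARE[archetype_id] if fossil_share is None else fossil_share
    nf = 1.0 - f
    shares = {
        "elec_coal": 0.50 * f,
        "elec_gas": 0.35 * f,
        "elec_oil": 0.15 * f,
        "elec_nuclear": 0.18 * nf,
        "elec_hydro": 0.42 * nf,
        "elec_wind": 0.25 * nf,
        "elec_solar": 0.15 * nf,
    }
    return ElectricityMix(archetype_id=archetype_id, shares=shares)


# ---------------------------------------------------------------------------
# Characterization table (illustrative, ReCiPe-2016-style magnitudes)
# ---------------------------------------------------------------------------


def default_characterization_table() -> CharacterizationTable:
    """Illustrative substance->midpoint->DALY factors.

    Midpoint factors are in each midpoint's reference unit per kg (kg
    CO2-eq, kg PM2.5-eq, kg 1,4-DCB-eq, m3, ...); endpoint factors are the
    hierarchic-perspective DALY conversions at a 100-year horizon.  CH4 is
    fossil methane at GWP100 = 29.8.
    """
    mf = {
        ("co2", "air", "global_warming"): 1.0,
        ("ch4", "air", "global_warming"): 29.8,
        ("cfc11", "air", "ozone_depletion"): 1.0,
        ("radionuclides", "air", "ionising_radiation"): 1.0,
        ("nox", "air", "ozone_formation"): 1.0,
        ("nmvoc", "air", "ozone_formation"): 0.18,
        ("nox", "air", "fine_pm"): 0.11,
        ("so2", "air", "fine_pm"): 0.29,
        ("pm25", "air", "fine_pm"): 1.0,
        ("benzene", "air", "carcinogenic_tox"): 280.0,
        ("dioxin", "air", "carcinogenic_tox"): 2.0e6,
        ("mercury", "air", "noncarcinogenic_tox"): 2.5e5,
        ("zinc", "soil", "noncarcinogenic_tox"): 3.0e4,
        ("zinc", "water", "noncarcinogenic_tox"): 3.0e4,
        ("water", "water", "water_use"): 1.0,
    }
    ef = {
        "global_warming": 9.28e-7,
        "ozone_depletion": 5.31e-4,
        "ionising_radiation": 8.5e-9,
        "ozone_formation": 9.1e-7,
        "fine_pm": 6.29e-4,
        "carcinogenic_tox": 3.32e-6,
        "noncarcinogenic_tox": 2.28e-7,
        "water_use": 2.22e-6,
    }
    return CharacterizationTable(midpoint_factors=mf, endpoint_factors=ef)


# ---------------------------------------------------------------------------
# Process inventories
# ---------------------------------------------------------------------------


def _technology_inventories() -> dict[str, ProcessInventory]:
    def inv(pid, tech=(), bio=()):
        return ProcessInventory(
            process_id=pid, unit="kWh",
            technosphere_inputs=tuple(tech), elementary_emissions=tuple(bio),
        )

    return {
        "elec_coal": inv(
            "elec_coal",
            tech=[("coal_supply", 0.40)],
            bio=[
                ("co2", "air", "short", 0.95),
                ("so2", "air", "short", 0.0035),
                ("nox", "air", "short", 0.0018),
                ("pm25", "air", "short", 4.0e-4),
                ("mercury", "air", "long", 3.0e-8),
            ],
        ),
        "elec_gas": inv(
            "elec_gas",
            tech=[("gas_supply", 0.20)],
            bio=[
                ("co2", "air", "short", 0.42),
                ("nox", "air", "short", 9.0e-4),
                ("ch4", "air", "short", 2.0e-4),
            ],
        ),
        "elec_oil": inv(
            "elec_oil",
            bio=[
                ("co2", "air", "short", 0.70),
                ("so2", "air", "short", 0.0025),
                ("nox", "air", "short", 0.0015),
                ("pm25", "air", "short", 2.0e-4),
            ],
        ),
        "elec_nuclear": inv(
            "elec_nuclear",
            bio=[
                ("radionuclides", "air", "long", 0.006),
                ("co2", "air", "short", 0.005),
            ],
        ),
        "elec_hydro": inv(
            "elec_hydro",
            bio=[("ch4", "air", "short", 1.5e-4), ("co2", "air", "short", 0.003)],
        ),
        "elec_wind": inv("elec_wind", bio=[("co2", "air", "short", 0.008)]),
        "elec_solar": inv(
            "elec_solar",
            bio=[("co2", "air", "short", 0.015), ("zinc", "soil", "long", 1.0e-8)],
        ),
    }


def _support_inventories() -> list[ProcessInventory]:
    def inv(pid, unit, tech=(), bio=()):
        return ProcessInventory(
            process_id=pid, unit=unit,
            technosphere_inputs=tuple(tech), elementary_emissions=tuple(bio),
        )

    return [
        inv("coal_supply", "kg", bio=[
            ("ch4", "air", "short", 0.004), ("pm25", "air", "short", 2.0e-5),
        ]),
        inv("gas_supply", "kg", bio=[
            ("ch4", "air", "short", 0.012), ("co2", "air", "short", 0.05),
        ]),
        inv("diesel_supply", "kg", bio=[
            ("co2", "air", "short", 0.40), ("nmvoc", "air", "short", 0.002),
        ]),
        inv("diesel_combustion", "kg", tech=[("diesel_supply", 1.0)], bio=[
            ("co2", "air", "short", 3.16),
            ("nox", "air", "short", 0.035),
            ("pm25", "air", "short", 0.0012),
            ("so2", "air", "short", 8.0e-4),
        ]),
        inv("transport_truck", "tkm", tech=[("diesel_combustion", 0.028)]),
        inv("glass_production", "kg",
            tech=[("electricity_grid", 0.30)],
            bio=[
                ("co2", "air", "short", 1.0),
                ("so2", "air", "short", 0.0018),
                ("nox", "air", "short", 0.0012),
                ("pm25", "air", "short", 2.5e-4),
            ]),
        inv("glass_disposal", "kg", tech=[("diesel_combustion", 0.002)], bio=[
            ("co2", "air", "short", 0.02),
        ]),
        inv("hand_wash", "wash-cycle",
            tech=[("electricity_grid", 0.11)],
            bio=[("water", "water", "short", 0.008)]),
        inv("dishwasher_wash", "wash-cycle",
            tech=[("electricity_grid", 0.05)],
            bio=[("water", "water", "short", 5.0e-4)]),
        inv("industrial_wash", "wash-cycle",
            tech=[("electricity_grid", 0.008)],
            bio=[("water", "water", "short", 2.0e-4)]),
    ]


# per-Mt stage templates: (electricity kWh, diesel kg, emissions)
# emissions: substance, compartment, term, kg (or m3 for water) per Mt
_STAGE_TEMPLATES: dict[str, tuple[float, float, list[tuple[str, str, str, float]]]] = {
    "production": (1.0e9, 2.0e6, [
        ("co2", "air", "short", 2.30e9),
        ("ch4", "air", "short", 9.0e6),
        ("so2", "air", "short", 4.5e6),
        ("nox", "air", "short", 3.5e6),
        ("pm25", "air", "short", 1.1e6),
        ("nmvoc", "air", "short", 4.0e6),
        ("benzene", "air", "short", 1.6e6),
        ("mercury", "air", "long", 6.0e2),
        ("zinc", "soil", "long", 1.2e5),
        ("water", "water", "short", 3.0e6),
        ("cfc11", "air", "short", 1.5e2),
    ]),
    "collection": (0.0, 3.5e6, []),
    "sorting": (6.0e7, 5.0e5, [("pm25", "air", "short", 2.0e4)]),
    "mechanical_recycling_closed": (5.0e8, 0.0, [
        ("co2", "air", "short", 1.0e8),
        ("pm25", "air", "short", 8.0e4),
        ("zinc", "water", "long", 5.0e3),
        ("water", "water", "short", 8.0e5),
    ]),
    "mechanical_recycling_open": (4.0e8, 0.0, [
        ("co2", "air", "short", 9.0e7),
        ("pm25", "air", "short", 7.0e4),
        ("zinc", "water", "long", 5.0e3),
        ("water", "water", "short", 7.0e5),
    ]),
    "chemical_recycling": (6.0e8, 0.0, [
        ("co2", "air", "short", 9.0e8),
        ("ch4", "air", "short", 2.0e6),
        ("pm25", "air", "short", 2.0e5),
        ("benzene", "air", "short", 1.0e6),
    ]),
    "incineration": (2.0e7, 0.0, [
        ("co2", "air", "short", 2.90e9),
        ("so2", "air", "short", 2.0e5),
        ("nox", "air", "short", 8.0e5),
        ("pm25", "air", "short", 1.5e5),
        ("dioxin", "air", "short", 2.0),
    ]),
    "engineered_landfill": (1.0e6, 8.0e5, [
        ("ch4", "air", "long", 6.0e6),
        ("zinc", "water", "long", 2.0e4),
    ]),
    "dumpsite": (0.0, 0.0, [
        ("ch4", "air", "long", 1.5e7),
        ("zinc", "water", "long", 8.0e4),
        ("pm25", "air", "short", 3.0e5),
        ("benzene", "air", "long", 2.0e5),
    ]),
    "open_burning": (0.0, 0.0, [
        ("co2", "air", "short", 2.75e9),
        ("ch4", "air", "short", 1.2e7),
        ("pm25", "air", "short", 9.0e6),
        ("nox", "air", "short", 3.0e6),
        ("so2", "air", "short", 5.0e5),
        ("dioxin", "air", "short", 2.5e2),
        ("benzene", "air", "short", 8.0e5),
    ]),
    "aquatic_pollution": (0.0, 0.0, [
        ("benzene", "air", "long", 3.0e4),
        ("zinc", "water", "long", 5.0e3),
    ]),
    "terrestrial_pollution": (0.0, 0.0, [
        ("benzene", "air", "long", 2.0e4),
        ("zinc", "soil", "long", 4.0e3),
    ]),
}

# substitute lifecycles, per Mt (electricity kWh, diesel kg, emissions)
_SUBSTITUTE_TEMPLATES = {
    "paper": (3.0e8, 2.0e6, [
        ("co2", "air", "short", 1.30e9),
        ("so2", "air", "short", 2.0e6),
        ("pm25", "air", "short", 4.0e5),
        ("water", "water", "short", 5.0e6),
        ("zinc", "water", "long", 1.0e4),
    ]),
    "coated_paper": (3.6e8, 2.2e6, [
        ("co2", "air", "short", 1.65e9),
        ("so2", "air", "short", 2.4e6),
        ("pm25", "air", "short", 5.0e5),
        ("water", "water", "short", 5.5e6),
        ("zinc", "water", "long", 1.2e4),
    ]),
    "polylactide": (8.0e8, 4.0e6, [
        ("co2", "air", "short", 2.20e9),
        ("pm25", "air", "short", 3.0e6),
        ("nox", "air", "short", 4.0e6),
        ("water", "water", "short", 2.0e7),
        ("benzene", "air", "short", 6.0e5),
    ]),
    "lower_grade_polymer": (8.0e8, 1.5e6, [
        ("co2", "air", "short", 2.0e9),
        ("so2", "air", "short", 3.6e6),
        ("nox", "air", "short", 2.8e6),
        ("pm25", "air", "short", 9.0e5),
        ("benzene", "air", "short", 1.3e6),
        ("zinc", "soil", "long", 1.0e5),
    ]),
    "fuel": (5.0e7, 0.0, [
        ("co2", "air", "short", 5.0e8),
        ("nmvoc", "air", "short", 2.0e6),
        ("pm25", "air", "short", 5.0e4),
    ]),
}

# polymer-specific toxic-emission multiplier (PVC routes more chlorinated
# and metal-bearing emissions)
_TOX_SUBSTANCES = {"benzene", "dioxin", "mercury", "zinc"}
_PVC_TOX_MULTIPLIER = 3.0


def _polymer_inventories(
    rng: np.random.Generator, emission_scale: float
) -> dict[tuple[str, str], ProcessInventory]:
    """Per-polymer, per-stage inventories: template x polymer variation."""
    out: dict[tuple[str, str], ProcessInventory] = {}
    for polymer in POLYMERS:
        for stage, (kwh, diesel, emissions) in _STAGE_TEMPLATES.items():
            scale = float(rng.uniform(0.85, 1.15))
            tech = []
            if kwh:
                tech.append(("electricity_grid", kwh * scale))
            if diesel:
                tech.append(("diesel_combustion", diesel * scale))
            bio = []
            for sub, comp, term, amt in emissions:
                mult = scale * emission_scale
                if polymer == "pvc" and sub in _TOX_SUBSTANCES:
                    mult *= _PVC_TOX_MULTIPLIER
                bio.append((sub, comp, term, amt * mult))
            out[(polymer, stage)] = ProcessInventory(
                process_id=f"{polymer}@{stage}", unit="Mt",
                technosphere_inputs=tuple(tech),
                elementary_emissions=tuple(bio),
            )
        for stage in ZERO_EFFECT_STAGES:
            out[(polymer, stage)] = ProcessInventory(
                process_id=f"{polymer}@{stage}", unit="Mt"
            )
    return out


def _profiles_and_compositions() -> tuple[
    dict[str, PolymerProfile], dict[str, CategoryComposition]
]:
    profiles = {
        "water_bottle": PolymerProfile("water_bottle", {"pet": 0.92, "hdpe": 0.08}),
        "serviceware": PolymerProfile("serviceware", {"pp": 0.55, "ps": 0.45}),
        "rigid_container": PolymerProfile(
            "rigid_container", {"hdpe": 0.50, "pp": 0.35, "pvc": 0.15}
        ),
        "carrier_bag": PolymerProfile("carrier_bag", {"ldpe": 0.80, "hdpe": 0.20}),
        "film_wrap": PolymerProfile("film_wrap", {"ldpe": 0.65, "pp": 0.35}),
        "sachet": PolymerProfile(
            "sachet", {"pet": 0.30, "ldpe": 0.30, "pp": 0.15, "pvc": 0.25}
        ),
        "laminate": PolymerProfile(
            "laminate", {"pet": 0.25, "ldpe": 0.25, "pvc": 0.35, "ps": 0.15}
        ),
    }
    compositions = {
        "rigid_mono": CategoryComposition(
            "rigid_mono",
            {"water_bottle": 0.40, "serviceware": 0.25, "rigid_container": 0.35},
        ),
        "flexible_mono": CategoryComposition(
            "flexible_mono", {"carrier_bag": 0.45, "film_wrap": 0.55}
        ),
        # routes proportionally more PVC than the other categories
        "multilayer_multi": CategoryComposition(
            "multilayer_multi", {"sachet": 0.55, "laminate": 0.45}
        ),
    }
    return profiles, compositions


def _reuse_specs() -> dict[str, ReuseSystemSpec]:
    return {
        "household_reuse": ReuseSystemSpec(
            system_id="household_reuse",
            container_mass_kg=0.35,
            lifespan_uses=200,
            uses_per_year=300,
            washing_shares=dict(_WASH_SHARES),
            transport_tkm_per_year=0.0,
            end_of_life_shares={"glass_disposal": 1.0},
        ),
        "door_to_door_refill": ReuseSystemSpec(
            system_id="door_to_door_refill",
            container_mass_kg=0.50,
            lifespan_uses=300,
            uses_per_year=300,
            # refill-system washing is industrial: no hand washing
            washing_shares={a: (0.0, 1.0) for a in ARCHETYPES},
            transport_tkm_per_year=3.0,
            end_of_life_shares={"glass_disposal": 1.0},
        ),
    }


# ---------------------------------------------------------------------------
# Ground-truth oracle: direct supply-chain expansion
# ---------------------------------------------------------------------------


def _expand_emissions(
    inv: ProcessInventory,
    by_id: dict[str, ProcessInventory],
    amount: float,
    acc: dict[tuple[str, str, str], float],
    depth: int = 0,
) -> None:
    if depth > 10:
        raise SchemaError("expansion depth exceeded: generated network has a cycle?")
    for s, c, t, a in inv.elementary_emissions:
        acc[(s, c, t)] = acc.get((s, c, t), 0.0) + a * amount
    for pid, a in inv.technosphere_inputs:
        if pid not in by_id:
            continue  # cut-off input: zero upstream burden
        _expand_emissions(by_id[pid], by_id, a * amount, acc, depth + 1)


def _truth_dalys(
    inv: ProcessInventory,
    by_id: dict[str, ProcessInventory],
    table: CharacterizationTable,
) -> float:
    acc: dict[tuple[str, str, str], float] = {}
    _expand_emissions(inv, by_id, 1.0, acc)
    if not acc:
        return 0.0
    g = pd.Series(
        list(acc.values()),
        index=pd.MultiIndex.from_tuples(
            list(acc.keys()), names=["substance", "compartment", "term"]
        ),
    )
    total, _ = total_dalys(characterize(g, table))
    return total


# ---------------------------------------------------------------------------
# World assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticWorld:
    """Everything gen_world emits, plus the stored ground truth."""

    config: WorldConfig
    table: CharacterizationTable
    mixes: dict[str, ElectricityMix]
    technology_inventories: dict[str, ProcessInventory]
    support_inventories: list[ProcessInventory]
    polymer_inventories: dict[tuple[str, str], ProcessInventory]
    profiles: dict[str, PolymerProfile]
    compositions: dict[str, CategoryComposition]
    reuse_specs: dict[str, ReuseSystemSpec]
    factor_table: FactorTable
    truth_dalys: dict[tuple[str, str, str], float]
    substitution_specs: dict[str, SubstitutionSpec]
    credit_rules: tuple[CreditRule, ...]

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "n_unit_factors": len(self.factor_table.keys()),
            "midpoints": list(MIDPOINTS),
        }


def default_substitution_specs() -> dict[str, SubstitutionSpec]:
    """1:1 mass substitution for single-use materials (sensitivity ranges
    0.4-9.0 for paper-based, 0.8-1.4 for compostables); packaging-intensity
    conversion for reuse systems (service-years per Mt displaced)."""
    return {
        "paper": SubstitutionSpec("paper", 1.0, (0.4, 9.0), stage_id="lifecycle"),
        "coated_paper": SubstitutionSpec(
            "coated_paper", 1.0, (0.4, 9.0), stage_id="lifecycle"
        ),
        "polylactide": SubstitutionSpec(
            "polylactide", 1.0, (0.8, 1.4), stage_id="lifecycle"
        ),
        "household_reuse": SubstitutionSpec(
            "household_reuse", 2.5e7, stage_id="service"
        ),
        "door_to_door_refill": SubstitutionSpec(
            "door_to_door_refill", 2.5e7, stage_id="service"
        ),
    }


def default_credit_rules() -> tuple[CreditRule, ...]:
    """Avoided burdens: closed-loop recyclate displaces the same category's
    primary production, open-loop displaces a lower-grade polymer, and
    waste-to-fuel pyrolysis displaces fuel production."""
    return (
        CreditRule("mechanical_recycling_closed", SAME_MATERIAL, 0.80),
        CreditRule("mechanical_recycling_open", "lower_grade_polymer", 0.70),
        CreditRule("chemical_recycling", "fuel", 0.60),
    )


def gen_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a solvable synthetic world with stored ground truth.

    Unit factors for every (material, stage, archetype) are computed twice:
    through the full pipeline (regionalize -> matrix solve -> characterize)
    into the factor table, and by direct supply-chain expansion into
    ``truth_dalys`` for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    table = default_characterization_table()

    def scale_emissions(inv: ProcessInventory) -> ProcessInventory:
        if config.emission_scale == 1.0:
            return inv
        return dataclasses.replace(
            inv,
            elementary_emissions=tuple(
                (s, c, t, a * config.emission_scale)
                for s, c, t, a in inv.elementary_emissions
            ),
        )

    techs = {k: scale_emissions(v) for k, v in _technology_inventories().items()}
    supports = [scale_emissions(s) for s in _support_inventories()]
    support_by_id = {s.process_id: s for s in supports}
    polymer_invs = _polymer_inventories(rng, config.emission_scale)
    profiles, compositions = _profiles_and_compositions()
    mixes = {a: electricity_mix(a) for a in ARCHETYPES}
    reuse_specs = _reuse_specs()

    factors: list[UnitImpactFactor] = []
    truth: dict[tuple[str, str, str], float] = {}

    def upstream_ids(mix: ElectricityMix) -> dict[str, ProcessInventory]:
        by_id = dict(techs)
        by_id.update(support_by_id)
        return by_id

    for archetype in ARCHETYPES:
        mix = mixes[archetype]
        by_id = upstream_ids(mix)

        # plastics categories through every lifecycle stage
        for category in CATEGORIES:
            comp = compositions[category]
            for stage in STAGES:
                inv = compose_category_inventory(
                    comp, profiles, polymer_invs, stage
                )
                f = compute_unit_factor(
                    category, stage, archetype, inv, table,
                    mix=mix, technology_inventories=techs,
                    support_inventories=supports,
                )
                factors.append(f)
                reg = (
                    regionalize_electricity(inv, mix, techs)
                    if any(p == "electricity_grid" for p, _ in inv.technosphere_inputs)
                    else inv
                )
                truth[(category, stage, archetype)] = _truth_dalys(reg, by_id, table)

        # single-use substitutes and credit materials, whole lifecycle per Mt
        for material, (kwh, diesel, emissions) in _SUBSTITUTE_TEMPLATES.items():
            stage = "lifecycle" if material in SINGLE_USE_SUBSTITUTES else "production"
            tech_in = []
            if kwh:
                tech_in.append(("electricity_grid", kwh))
            if diesel:
                tech_in.append(("diesel_combustion", diesel))
            inv = ProcessInventory(
                process_id=f"{material}@{stage}", unit="Mt",
                technosphere_inputs=tuple(tech_in),
                elementary_emissions=tuple(
                    (s, c, t, a * config.emission_scale) for s, c, t, a in emissions
                ),
            )
            f = compute_unit_factor(
                material, stage, archetype, inv, table,
                mix=mix, technology_inventories=techs,
                support_inventories=supports,
            )
            factors.append(f)
            reg = regionalize_electricity(inv, mix, techs) if kwh else inv
            truth[(material, stage, archetype)] = _truth_dalys(reg, by_id, table)

        # reusable-glass systems, per packaging service-year
        components = {
            "glass_production": support_by_id["glass_production"],
            "hand_wash": support_by_id["hand_wash"],
            "dishwasher_wash": support_by_id["dishwasher_wash"],
            "transport_truck": support_by_id["transport_truck"],
            "glass_disposal": support_by_id["glass_disposal"],
        }
        refill_components = dict(components)
        refill_components["dishwasher_wash"] = support_by_id["industrial_wash"]
        for system_id, comp_map in (
            ("household_reuse", components),
            ("door_to_door_refill", refill_components),
        ):
            f = reuse_system_factor(
                reuse_specs[system_id], archetype, comp_map, table,
                mix=mix, technology_inventories=techs,
                support_inventories=supports,
            )
            factors.append(f)
            truth[(system_id, "service", archetype)] = f.dalys_per_unit

    factor_table = FactorTable.from_factors(factors)
    return SyntheticWorld(
        config=config,
        table=table,
        mixes=mixes,
        technology_inventories=techs,
        support_inventories=supports,
        polymer_inventories=polymer_invs,
        profiles=profiles,
        compositions=compositions,
        reuse_specs=reuse_specs,
        factor_table=factor_table,
        truth_dalys=truth,
        substitution_specs=default_substitution_specs(),
        credit_rules=default_credit_rules(),
    )


# ---------------------------------------------------------------------------
# Flow generation
# ---------------------------------------------------------------------------

_SUBSTITUTE_ALLOCATION = {
    "paper": 0.35,
    "coated_paper": 0.15,
    "polylactide": 0.25,
    "household_reuse": 0.15,
    "door_to_door_refill": 0.10,
}


def _routing(
    params: dict[str, float], levers: ScenarioLevers, year: int
) -> dict[str, float]:
    """Stage shares of production mass for one archetype-year (sum to the
    node balances used by check_conservation)."""
    collect = min(
        params["collect"] + levers.collection_boost * levers.ramp_collection(year),
        0.99,
    )
    informal = params["informal"]
    boost = levers.recycling_boost * levers.ramp_recycling(year)
    r = levers.ramp(year)
    mech_closed = _BASE_ROUTES["mech_closed"] + 0.40 * boost
    mech_open = _BASE_ROUTES["mech_open"] + 0.40 * boost
    chemical = _BASE_ROUTES["chemical"] + 0.20 * boost
    incin = params["incin"] + levers.incineration_boost * r
    routed = mech_closed + mech_open + chemical + incin
    if routed > 0.95:
        raise SchemaError(
            f"sorting routes exceed available mass in {year}: {routed:.3f}"
        )
    landfill = 1.0 - routed
    return dict(
        collect=collect, informal=informal,
        mech_closed=mech_closed, mech_open=mech_open, chemical=chemical,
        incin=incin, landfill=landfill,
    )


def gen_flows(config: WorldConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point-estimate mass flows and displaced (substituted) masses.

    Returns ``(flows, displaced)``: flows in the canonical schema with
    ``replicate == "point"``; displaced with columns (year, scenario,
    archetype, category, substitute, displaced_mass_mt, replicate).
    Mass balance holds at every routing node by construction.
    """
    lo, hi = config.years
    years = np.arange(lo, hi + 1)
    flow_rows: list[tuple] = []
    disp_rows: list[tuple] = []
    for scenario in SCENARIOS:
        levers = config.levers[scenario]
        for archetype in ARCHETYPES:
            params = _ARCH_PARAMS[archetype]
            for category in CATEGORIES:
                base = (
                    config.demand_2016_mt
                    * params["demand"]
                    * _CATEGORY_SHARES[category]
                )
                for year in years:
                    growth = float(np.exp(config.bau_growth * (year - lo)))
                    ramp = levers.ramp(year)
                    cut = levers.production_cut * ramp
                    demand = base * growth * (1.0 - cut)
                    substituted = base * growth * cut * levers.substitution_share
                    route = _routing(params, levers, int(year))

                    collected = route["collect"] * demand
                    informal = route["informal"] * collected
                    formal = collected - informal
                    sorting = collected
                    mech_c = route["mech_closed"] * sorting
                    mech_o = route["mech_open"] * sorting
                    chem = route["chemical"] * sorting
                    incin = route["incin"] * sorting
                    landfill_sorted = route["landfill"] * sorting
                    uncollected = demand - collected
                    ob = _UNCOLLECTED["open_burning"] * uncollected
                    dump = _UNCOLLECTED["dumpsite"] * uncollected
                    litter = uncollected - ob - dump
                    aquatic = _LITTER_SPLIT["aquatic"] * litter
                    terrestrial = litter - aquatic
                    cleanup = _CLEANUP_SHARE * aquatic
                    landfill = landfill_sorted + cleanup

                    stage_mass = {
                        "production": demand,
                        "collection": formal,
                        "informal_collection": informal,
                        "sorting": sorting,
                        "mechanical_recycling_closed": mech_c,
                        "mechanical_recycling_open": mech_o,
                        "chemical_recycling": chem,
                        "incineration": incin,
                        "engineered_landfill": landfill,
                        "dumpsite": dump,
                        "open_burning": ob,
                        "littering": litter,
                        "beach_cleanup": cleanup,
                        "aquatic_pollution": aquatic,
                        "terrestrial_pollution": terrestrial,
                    }
                    for stage, mass in stage_mass.items():
                        flow_rows.append(
                            (int(year), scenario, archetype, category, stage,
                             float(mass), POINT_REPLICATE)
                        )
                    if substituted > 0:
                        for sub, alloc in _SUBSTITUTE_ALLOCATION.items():
                            disp_rows.append(
                                (int(year), scenario, archetype, category, sub,
                                 float(substituted * alloc), POINT_REPLICATE)
                            )
    flows = pd.DataFrame(
        flow_rows,
        columns=["year", "scenario", "archetype", "material", "stage",
                 "mass_mt", "replicate"],
    )
    displaced = pd.DataFrame(
        disp_rows,
        columns=["year", "scenario", "archetype", "category", "substitute",
                 "displaced_mass_mt", "replicate"],
    )
    return flows, displaced


def check_conservation(flows: pd.DataFrame) -> float:
    """Maximum node-balance residual (Mt) across all flow keys.

    Verifies, per (year, scenario, archetype, material, replicate):
    sorting = collection + informal collection; sorting's children sum back
    to sorting (cleaned-up litter enters landfill separately); production =
    sorting + open burning + dumpsite + littering; littering = aquatic +
    terrestrial pollution.
    """
    wide = flows.pivot_table(
        index=["year", "scenario", "archetype", "material", "replicate"],
        columns="stage", values="mass_mt", aggfunc="sum", fill_value=0.0,
    )
    res = np.zeros(len(wide))
    res = np.maximum(
        res,
        np.abs(
            wide["sorting"] - wide["collection"] - wide["informal_collection"]
        ),
    )
    sorted_children = (
        wide["mechanical_recycling_closed"]
        + wide["mechanical_recycling_open"]
        + wide["chemical_recycling"]
        + wide["incineration"]
        + (wide["engineered_landfill"] - wide["beach_cleanup"])
    )
    res = np.maximum(res, np.abs(sorted_children - wide["sorting"]))
    res = np.maximum(
        res,
        np.abs(
            wide["production"]
            - wide["sorting"]
            - wide["open_burning"]
            - wide["dumpsite"]
            - wide["littering"]
        ),
    )
    res = np.maximum(
        res,
        np.abs(
            wide["littering"]
            - wide["aquatic_pollution"]
            - wide["terrestrial_pollution"]
        ),
    )
    return float(np.max(res)) if len(res) else 0.0


def gen_replicates(
    config: WorldConfig,
    flows: pd.DataFrame | None = None,
    displaced: pd.DataFrame | None = None,
    n_replicates: int | None = None,
):
    """Yield seeded lognormal replicate perturbations of the point flows.

    Noise multipliers attach to the production source node — one
    independent lognormal draw per (scenario, archetype, category, year) —
    and propagate through the fixed routing shares, so each replicate
    remains mass-conserving at every node.  Yields
    ``(replicate_id, flows_r, displaced_r)`` lazily.
    """
    if flows is None or displaced is None:
        flows, displaced = gen_flows(config)
    n = config.n_replicates if n_replicates is None else n_replicates
    if n < 2:
        raise SchemaError(f"need at least 2 replicates, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF10]))
    key_cols = ["scenario", "archetype", "material", "year"]
    keys = flows[key_cols].drop_duplicates().reset_index(drop=True)
    dkey_cols = ["scenario", "archetype", "category", "year"]
    sigma = config.dispersion
    for r in range(n):
        rid = f"r{r:03d}"
        noise = keys.copy()
        noise["mult"] = np.exp(
            rng.normal(-0.5 * sigma**2, sigma, size=len(keys))
        )
        flows_r = flows.merge(noise, on=key_cols, how="left")
        flows_r["mass_mt"] = flows_r["mass_mt"] * flows_r["mult"]
        flows_r["replicate"] = rid
        flows_r = flows_r.drop(columns="mult")
        dn = noise.rename(columns={"material": "category"})
        displaced_r = displaced.merge(dn, on=dkey_cols, how="left")
        displaced_r["displaced_mass_mt"] = (
            displaced_r["displaced_mass_mt"] * displaced_r["mult"].fillna(1.0)
        )
        displaced_r["replicate"] = rid
        displaced_r = displaced_r.drop(columns="mult")
        yield rid, flows_r, displaced_r


def gen_reference_config(
    seed: int = 0,
) -> tuple[WorldConfig, dict[str, SubstitutionSpec], tuple[CreditRule, ...]]:
    """The shipped configuration emulating the modelled global system.

    Its outputs reproduce the documented structure: primary production is
    the rank-1 DALY contributor in BAU with open burning second; cumulative
    2016-2040 burdens order BAU > current commitments > collect & dispose >
    recycling > reduce & substitute > system change; the two
    demand-reduction scenarios peak around 2030-2032 and then decline.
    Absolute magnitudes are synthetic, not calibrated to any external data.
    """
    return WorldConfig(seed=seed), default_substitution_specs(), default_credit_rules()


# ---------------------------------------------------------------------------
# Serialization of a generated world (the CSV schemas consumed downstream)
# ---------------------------------------------------------------------------


def write_world(world: SyntheticWorld, directory) -> None:
    from pathlib import Path

    from .characterization import write_characterization_csv
    from .coupling import write_flows_csv
    from .inventory import write_inventories_csv, write_mixes_csv

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    invs = (
        list(world.polymer_inventories.values())
        + list(world.technology_inventories.values())
        + world.support_inventories
    )
    write_inventories_csv(invs, d / "inventories.csv")
    write_mixes_csv(world.mixes, d / "mixes.csv")
    write_characterization_csv(
        world.table, d / "midpoint_factors.csv", d / "endpoint_factors.csv"
    )
    world.factor_table.to_csv(d / "unit_factors.csv")
    flows, displaced = gen_flows(world.config)
    write_flows_csv(flows, d / "flows.csv")
    displaced.to_csv(d / "displaced.csv", index=False)
    with open(d / "manifest.json", "w") as fh:
        json.dump(world.manifest(), fh, indent=1, default=str)
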