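"""Unitary impact "building blocks".

A building block is the precomputed health impact of pushing one functional
unit of a material through one lifecycle stage in one geographical
archetype: DALYs per Mt for the three plastics categories and single-use
substitutes, DALYs per packaging service-year for the reusable-glass
systems.  Blocks are static — computed once from process inventories,
regionalized electricity mixes and a characterization table — and then act
as multipliers on mass flows.

Plastics categories are product mixes: each product has a polymer profile
(mass fractions of PET, HDPE, PVC, ...), and a category inventory is the
share-weighted combination of polymer inventories, normalized to 1 Mt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .characterization import (
    CharacterizationTable,
    MidpointVector,
    characterize,
    total_dalys,
)
from .constants import DIRECTION_AVOIDED, DIRECTION_INDUCED, MIDPOINTS
from .exceptions import MissingKeyError, SchemaError
from .inventory import (
    ElectricityMix,
    ProcessInventory,
    build_system,
    regionalize_electricity,
    solve_inventory,
)

__all__ = [
    "PolymerProfile",
    "CategoryComposition",
    "UnitImpactFactor",
    "ReuseSystemSpec",
    "FactorTable",
    "compose_category_inventory",
    "compute_unit_factor",
    "reuse_system_factor",
]

_SHARE_TOL = 1e-9


def _check_shares(shares: dict[str, float], what: str) -> None:
    total = sum(shares.values())
    if abs(total - 1.0) > _SHARE_TOL:
        raise SchemaError(f"{what} sum to {total:.12g}, expected 1")
    for key, s in shares.items():
        if s < 0:
            raise SchemaError(f"negative share {s} for {key!r} in {what}")


@dataclass(frozen=True)
class PolymerProfile:
    """Mass fractions of polymers making up one product type."""

    product_id: str
    polymer_fractions: dict[str, float]

    def __post_init__(self) -> None:
        _check_shares(
            self.polymer_fractions, f"polymer fractions of {self.product_id!r}"
        )


@dataclass(frozen=True)
class CategoryComposition:
    """Product mass shares of one plastics category (static over time)."""

    category_id: str
    product_shares: dict[str, float]

    def __post_init__(self) -> None:
        _check_shares(
            self.product_shares, f"product shares of category {self.category_id!r}"
        )

    def polymer_weights(
        self, profiles: dict[str, PolymerProfile]
    ) -> dict[str, float]:
        """Category-level polymer mass fractions (sum to 1)."""
        weights: dict[str, float] = {}
        for product, share in self.product_shares.items():
            if product not in profiles:
                raise MissingKeyError(f"no polymer profile for product {product!r}")
            for polymer, frac in profiles[product].polymer_fractions.items():
                weights[polymer] = weights.get(polymer, 0.0) + share * frac
        return weights


@dataclass(frozen=True)
class UnitImpactFactor:
    """DALYs (total and by midpoint) per functional unit of one block.

    ``direction`` distinguishes induced burdens from avoided-burden credits;
    avoided factors are stored as positive magnitudes and the sign is
    applied when flows are coupled.  ``activity_breakdown`` carries the
    production/washing/transport/end-of-life split for reuse systems.
    """

    material_id: str
    stage_id: str
    archetype_id: str
    dalys_per_unit: float
    midpoint_breakdown: MidpointVector
    direction: str = DIRECTION_INDUCED
    unit: str = "Mt"
    activity_breakdown: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in (DIRECTION_INDUCED, DIRECTION_AVOIDED):
            raise SchemaError(f"unknown direction {self.direction!r}")
        if not math.isfinite(self.dalys_per_unit):
            raise SchemaError("non-finite dalys_per_unit")
        if self.dalys_per_unit < 0:
            raise SchemaError(
                "factors are stored as magnitudes; negative total for "
                f"({self.material_id!r}, {self.stage_id!r}, {self.archetype_id!r})"
            )
        closure = sum(self.midpoint_breakdown.daly_values.values())
        if abs(closure - self.dalys_per_unit) > 1e-9 * max(
            1.0, abs(self.dalys_per_unit)
        ):
            raise SchemaError(
                f"midpoint closure violated: breakdown sums to {closure}, "
                f"total is {self.dalys_per_unit}"
            )
        if self.activity_breakdown is not None:
            s = sum(self.activity_breakdown.values())
            if abs(s - self.dalys_per_unit) > 1e-9 * max(1.0, abs(self.dalys_per_unit)):
                raise SchemaError(
                    f"activity breakdown sums to {s}, total is {self.dalys_per_unit}"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.material_id, self.stage_id, self.archetype_id)


@dataclass(frozen=True)
class ReuseSystemSpec:
    """Parameters of a reusable-glass packaging system.

    The functional unit is one packaging service-year: ``uses_per_year``
    container fills delivered over a year.  Container production and
    disposal are amortized over ``lifespan`` uses; washing happens at every
    use, split between hand and machine washing per archetype; the
    door-to-door refill system additionally carries distribution transport.
    """

    system_id: str
    container_mass_kg: float
    lifespan_uses: float
    uses_per_year: float
    washing_shares: dict[str, tuple[float, float]]  # archetype -> (hand, dishwasher)
    transport_tkm_per_year: float = 0.0
    end_of_life_shares: dict[str, float] = field(
        default_factory=lambda: {"glass_disposal": 1.0}
    )

    def __post_init__(self) -> None:
        if self.lifespan_uses < 1:
            raise SchemaError(
                f"container lifespan must be >= 1 use, got {self.lifespan_uses}"
            )
        if self.container_mass_kg <= 0 or self.uses_per_year <= 0:
            raise SchemaError("container mass and uses per year must be positive")
        for arch, (hand, dw) in self.washing_shares.items():
            if not (0 <= hand <= 1 and 0 <= dw <= 1):
                raise SchemaError(f"washing shares out of [0, 1] for {arch!r}")
            if abs(hand + dw - 1.0) > _SHARE_TOL:
                raise SchemaError(f"washing shares for {arch!r} do not sum to 1")
        _check_shares(
            self.end_of_life_shares, f"end-of-life shares of {self.system_id!r}"
        )


def compose_category_inventory(
    composition: CategoryComposition,
    profiles: dict[str, PolymerProfile],
    polymer_inventories: dict[tuple[str, str], ProcessInventory],
    stage_id: str,
) -> ProcessInventory:
    """Mass-share-weighted polymer inventory for 1 Mt of a category.

    The weight of polymer p is sum over products of (product share x
    polymer fraction); the combined inventory is the weighted sum of the
    per-Mt polymer inventories at the requested stage.
    """
    weights = composition.polymer_weights(profiles)
    missing = sorted(
        p for p in weights if (p, stage_id) not in polymer_inventories
    )
    if missing:
        raise MissingKeyError(
            f"no inventory at stage {stage_id!r} for polymers: "
            + ", ".join(repr(m) for m in missing)
        )
    tech: dict[str, float] = {}
    bio: dict[tuple[str, str, str], float] = {}
    unit = None
    for polymer, w in sorted(weights.items()):
        inv = polymer_inventories[(polymer, stage_id)]
        unit = unit or inv.unit
        if inv.unit != unit:
            raise SchemaError(
                f"unit mismatch composing {composition.category_id!r} at "
                f"{stage_id!r}: {inv.unit!r} vs {unit!r}"
            )
        for pid, amt in inv.technosphere_inputs:
            tech[pid] = tech.get(pid, 0.0) + w * amt
        for s, c, t, amt in inv.elementary_emissions:
            bio[(s, c, t)] = bio.get((s, c, t), 0.0) + w * amt
    return ProcessInventory(
        process_id=f"{composition.category_id}@{stage_id}",
        unit=unit or "Mt",
        technosphere_inputs=tuple(sorted(tech.items())),
        elementary_emissions=tuple(
            (s, c, t, a) for (s, c, t), a in sorted(bio.items())
        ),
    )


def compute_unit_factor(
    material_id: str,
    stage_id: str,
    archetype_id: str,
    stage_inventory: ProcessInventory,
    table: CharacterizationTable,
    *,
    mix: ElectricityMix | None = None,
    technology_inventories: dict[str, ProcessInventory] | None = None,
    support_inventories: list[ProcessInventory] | None = None,
    cutoff_ids: frozenset[str] | set[str] = frozenset(),
    demand: float = 1.0,
    direction: str = DIRECTION_INDUCED,
    unit: str = "Mt",
) -> UnitImpactFactor:
    """One building block: regionalize -> solve inventory -> characterize.

    ``support_inventories`` supply the upstream processes (fuels,
    transport, electricity technologies); when ``mix`` is given and the
    stage inventory draws aggregate grid electricity, that input is split
    into technology inputs weighted by the archetype's mix first.

    A zero-effect stage (empty inventory) yields a factor of exactly zero
    across all midpoints.
    """
    def _regionalize(p: ProcessInventory) -> ProcessInventory:
        if not any(pid == "electricity_grid" for pid, _ in p.technosphere_inputs):
            return p
        if mix is None:
            return p
        if not technology_inventories:
            raise MissingKeyError(
                "regionalization requested but no technology inventories given"
            )
        return regionalize_electricity(p, mix, technology_inventories)

    inv = _regionalize(stage_inventory)
    inventories = [inv]
    if technology_inventories:
        inventories.extend(
            t for t in technology_inventories.values() if t.process_id != inv.process_id
        )
    if support_inventories:
        have = {i.process_id for i in inventories}
        inventories.extend(
            _regionalize(s) for s in support_inventories if s.process_id not in have
        )
    system = build_system(inventories, cutoff_ids=cutoff_ids)
    g = solve_inventory(system, {inv.process_id: demand})
    mv = characterize(g, table)
    total, _ = total_dalys(mv)
    return UnitImpactFactor(
        material_id=material_id,
        stage_id=stage_id,
        archetype_id=archetype_id,
        dalys_per_unit=total,
        midpoint_breakdown=mv,
        direction=direction,
        unit=unit,
    )


def reuse_system_factor(
    spec: ReuseSystemSpec,
    archetype_id: str,
    component_inventories: dict[str, ProcessInventory],
    table: CharacterizationTable,
    *,
    mix: ElectricityMix | None = None,
    technology_inventories: dict[str, ProcessInventory] | None = None,
    support_inventories: list[ProcessInventory] | None = None,
) -> UnitImpactFactor:
    """Impact per packaging service-year of a reusable-glass system.

    Components are unit processes named ``glass_production`` (per kg),
    ``hand_wash`` and ``dishwasher_wash`` (per wash-cycle),
    ``transport_truck`` (per tkm) and one process per end-of-life route
    (per kg).  Container production and disposal are amortized over the
    container lifespan; washing scales with annual uses.
    """
    if archetype_id not in spec.washing_shares:
        raise MissingKeyError(
            f"no washing profile for archetype {archetype_id!r} in "
            f"system {spec.system_id!r}"
        )

    def component(name: str, amount: float) -> MidpointVector:
        if amount == 0.0:
            return MidpointVector.zeros()
        if name not in component_inventories:
            raise MissingKeyError(
                f"reuse system {spec.system_id!r} needs component {name!r}"
            )
        f = compute_unit_factor(
            spec.system_id,
            name,
            archetype_id,
            component_inventories[name],
            table,
            mix=mix,
            technology_inventories=technology_inventories,
            support_inventories=support_inventories,
            demand=amount,
            unit="service-year",
        )
        return f.midpoint_breakdown

    containers = spec.uses_per_year / spec.lifespan_uses
    hand, dw = spec.washing_shares[archetype_id]
    parts = {
        "production": component(
            "glass_production", containers * spec.container_mass_kg
        ),
        "washing": component("hand_wash", spec.uses_per_year * hand)
        + component("dishwasher_wash", spec.uses_per_year * dw),
        "transport": component("transport_truck", spec.transport_tkm_per_year),
    }
    eol = MidpointVector.zeros()
    for route, share in spec.end_of_life_shares.items():
        eol = eol + component(route, containers * spec.container_mass_kg * share)
    parts["end_of_life"] = eol

    mv = MidpointVector.zeros()
    for part in parts.values():
        mv = mv + part
    total, _ = total_dalys(mv)
    return UnitImpactFactor(
        material_id=spec.system_id,
        stage_id="service",
        archetype_id=archetype_id,
        dalys_per_unit=total,
        midpoint_breakdown=mv,
        unit="service-year",
        activity_breakdown={
            name: sum(part.daly_values.values()) for name, part in parts.items()
        },
    )


class FactorTable:
    """Long-format building-block table with fast key lookup.

    One row per (material, stage, archetype, midpoint); this is also the
    import schema for externally supplied unit-factor files, enabling
    exact-reproduction runs on real appendix data.
    """

    COLUMNS = [
        "material_id",
        "stage_id",
        "archetype_id",
        "midpoint_id",
        "value_per_unit",
        "dalys_per_unit",
        "direction",
    ]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"factor table missing columns: {sorted(missing)}")
        bad = set(df["midpoint_id"]) - set(MIDPOINTS)
        if bad:
            raise SchemaError(f"factor table has unknown midpoints: {sorted(bad)}")
        self.df = df.reset_index(drop=True)
        totals = df.groupby(
            ["material_id", "stage_id", "archetype_id"], sort=False
        )["dalys_per_unit"].sum()
        self._totals: dict[tuple[str, str, str], float] = totals.to_dict()

    @classmethod
    def from_factors(cls, factors: list[UnitImpactFactor]) -> "FactorTable":
        rows = []
        for f in factors:
            for mid in MIDPOINTS:
                rows.append(
                    (
                        f.material_id,
                        f.stage_id,
                        f.archetype_id,
                        mid,
                        f.midpoint_breakdown.values.get(mid, 0.0),
                        f.midpoint_breakdown.daly_values.get(mid, 0.0),
                        f.direction,
                    )
                )
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def keys(self) -> set[tuple[str, str, str]]:
        return set(self._totals)

    def dalys_per_unit(
        self, material_id: str, stage_id: str, archetype_id: str
    ) -> float:
        key = (material_id, stage_id, archetype_id)
        if key not in self._totals:
            raise MissingKeyError(f"no unit factor for {key}")
        return self._totals[key]

    def midpoint_dalys(self) -> pd.DataFrame:
        """Pivot: one row per key, one column per midpoint (DALY/unit)."""
        wide = self.df.pivot_table(
            index=["material_id", "stage_id", "archetype_id"],
            columns="midpoint_id",
            values="dalys_per_unit",
            aggfunc="sum",
            fill_value=0.0,
        )
        return wide.reindex(columns=list(MIDPOINTS), fill_value=0.0)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FactorTable":
        return cls(pd.read_csv(path))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FactorTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.df.sort_values(self.COLUMNS[:4]).reset_index(drop=True),
                other.df.sort_values(self.COLUMNS[:4]).reset_index(drop=True),
            )
        except AssertionError:
            return False
        return True
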