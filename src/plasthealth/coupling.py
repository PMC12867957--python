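"""Coupling mass flows to unit impact factors.

The material-flow dataset supplies annual masses (Mt) of each plastics
category through each lifecycle stage, per scenario and geographical
archetype.  Coupling multiplies each flow by the matching building block
(DALYs per Mt), books avoided-burden credits for recycling and
waste-to-fuel (negative records against the displaced production), expands
substituted plastics into substitute-material flows, and aggregates the
resulting DALY ledger by year, scenario, archetype, material, stage,
midpoint and direction.

Sign convention: induced records have positive effective mass and DALYs;
avoided records carry a negative effective mass against the avoided
material's production factor, so every ledger row obeys
``dalys = mass x factor`` and all breakdowns (including per-substance)
remain exact linear re-aggregations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import FactorTable
from .constants import (
    DIRECTION_AVOIDED,
    DIRECTION_INDUCED,
    MIDPOINTS,
    SCENARIOS,
)
from .exceptions import MissingKeyError, SchemaError

__all__ = [
    "CreditRule",
    "SubstitutionSpec",
    "ScenarioResult",
    "couple",
    "apply_credits",
    "apply_substitution",
    "aggregate",
    "percent_reduction",
    "contribution_analysis",
    "FLOW_COLUMNS",
    "read_flows_csv",
    "write_flows_csv",
]

FLOW_COLUMNS = ["year", "scenario", "archetype", "material", "stage", "mass_mt", "replicate"]
KEY_COLUMNS = ["year", "scenario", "archetype", "material", "stage", "replicate"]
DALY_COLUMNS = [f"daly_{m}" for m in MIDPOINTS]
POINT_REPLICATE = "point"

#: sentinel avoided-material id: the credit displaces the triggering flow's
#: own material (closed-loop recycling averts same-category virgin production)
SAME_MATERIAL = "__same__"


@dataclass(frozen=True)
class CreditRule:
    """Avoided-burden credit booked when mass passes a trigger stage.

    Each Mt through ``trigger_stage`` averts ``yield_fraction`` Mt of
    ``avoided_material`` production (virgin polymer for closed-loop
    recycling, a lower-grade polymer for open-loop recycling, fuel for
    waste-to-fuel pyrolysis).
    """

    trigger_stage: str
    avoided_material: str
    yield_fraction: float
    avoided_stage: str = "production"

    def __post_init__(self) -> None:
        if not 0.0 <= self.yield_fraction <= 1.0:
            raise SchemaError(
                f"credit yield must be in [0, 1], got {self.yield_fraction}"
            )


@dataclass(frozen=True)
class SubstitutionSpec:
    """Conversion of displaced plastic mass into a substitute's flows.

    ``ratio`` is Mt of substitute per Mt of displaced plastic for
    single-use materials, or packaging service-years per Mt displaced for
    the reuse systems; ``ratio_range`` brackets it for sensitivity sweeps.
    """

    substitute_id: str
    ratio: float
    ratio_range: tuple[float, float] | None = None
    stage_id: str = "lifecycle"

    def __post_init__(self) -> None:
        if not (self.ratio > 0 and math.isfinite(self.ratio)):
            raise SchemaError(
                f"substitution ratio must be positive, got {self.ratio} "
                f"for {self.substitute_id!r}"
            )
        if self.ratio_range is not None:
            low, high = self.ratio_range
            if not (0 < low <= self.ratio <= high):
                raise SchemaError(
                    f"ratio range ({low}, {high}) must bracket ratio "
                    f"{self.ratio} for {self.substitute_id!r}"
                )

    def with_ratio(self, ratio: float) -> "SubstitutionSpec":
        return SubstitutionSpec(
            substitute_id=self.substitute_id,
            ratio=ratio,
            ratio_range=None,
            stage_id=self.stage_id,
        )


def _validate_flows(flows: pd.DataFrame) -> pd.DataFrame:
    missing = set(FLOW_COLUMNS) - set(flows.columns)
    if missing:
        raise SchemaError(f"flow table missing columns: {sorted(missing)}")
    if (flows["mass_mt"] < 0).any():
        bad = flows.loc[flows["mass_mt"] < 0].iloc[0]
        raise SchemaError(
            f"negative mass {bad['mass_mt']} for "
            f"({bad['material']}, {bad['stage']}, year {bad['year']})"
        )
    return flows


def couple(flows: pd.DataFrame, factors: FactorTable) -> pd.DataFrame:
    """Multiply every flow record by its unit factor.

    Returns the DALY ledger: one row per flow with total and per-midpoint
    DALYs, ``direction`` set to induced and ``source_stage`` equal to the
    flow's own stage.  A flow whose (material, stage, archetype) key has no
    factor is a hard error listing the orphan keys — a silent zero would be
    indistinguishable from a genuine zero-effect stage.
    """
    flows = _validate_flows(flows)
    ledger = flows.copy()
    if ledger.empty:
        ledger["dalys"] = pd.Series(dtype=float)
        for col in DALY_COLUMNS:
            ledger[col] = pd.Series(dtype=float)
        ledger["direction"] = pd.Series(dtype=object)
        ledger["source_stage"] = pd.Series(dtype=object)
        return ledger

    keys = set(
        zip(ledger["material"], ledger["stage"], ledger["archetype"])
    )
    orphans = sorted(keys - factors.keys())
    if orphans:
        raise MissingKeyError(
            f"{len(orphans)} flow key(s) have no unit factor: "
            + "; ".join(map(str, orphans[:10]))
            + ("; ..." if len(orphans) > 10 else "")
        )
    wide = factors.midpoint_dalys()
    wide.columns = DALY_COLUMNS
    wide = wide.reset_index().rename(
        columns={"material_id": "material", "stage_id": "stage", "archetype_id": "archetype"}
    )
    ledger = ledger.merge(wide, on=["material", "stage", "archetype"], how="left")
    for col in DALY_COLUMNS:
        ledger[col] = ledger[col].to_numpy() * ledger["mass_mt"].to_numpy()
    ledger["dalys"] = ledger[DALY_COLUMNS].sum(axis=1)
    ledger["direction"] = DIRECTION_INDUCED
    ledger["source_stage"] = ledger["stage"]
    return ledger


def apply_credits(
    ledger: pd.DataFrame,
    flows: pd.DataFrame,
    rules: list[CreditRule] | tuple[CreditRule, ...],
    factors: FactorTable,
) -> pd.DataFrame:
    """Append avoided-burden records for every credit rule.

    Each flow through a rule's trigger stage books a negative effective
    mass of ``yield x mass`` against the avoided material's production
    factor; induced records are untouched.
    """
    flows = _validate_flows(flows)
    factor_stages = {stage for _, stage, _ in factors.keys()}
    pieces = [ledger]
    for rule in rules:
        flow_stages = set(flows["stage"].unique())
        if rule.trigger_stage not in flow_stages | factor_stages:
            raise SchemaError(
                f"credit rule references unknown stage {rule.trigger_stage!r}"
            )
        sel = flows.loc[flows["stage"] == rule.trigger_stage]
        if sel.empty or rule.yield_fraction == 0.0:
            continue
        credit = sel.copy()
        if rule.avoided_material != SAME_MATERIAL:
            credit["material"] = rule.avoided_material
        credit["stage"] = rule.avoided_stage
        credit["mass_mt"] = credit["mass_mt"] * rule.yield_fraction
        piece = couple(credit[FLOW_COLUMNS], factors)
        # credits are negative records against the avoided production
        for col in ["dalys", *DALY_COLUMNS, "mass_mt"]:
            piece[col] = -piece[col]
        piece["direction"] = DIRECTION_AVOIDED
        piece["source_stage"] = rule.trigger_stage
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def apply_substitution(
    displaced: pd.DataFrame,
    specs: dict[str, SubstitutionSpec],
    factors: FactorTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand displaced plastics into substitute flows and their ledger.

    ``displaced`` has columns (year, scenario, archetype, substitute,
    displaced_mass_mt, replicate): the plastic mass each substitute
    displaces.  Substitute amount = ratio x displaced mass (service-years
    for reuse systems).  The displaced plastics' own lifecycle records are
    already absent from the flow dataset by construction.
    """
    required = {"year", "scenario", "archetype", "substitute", "displaced_mass_mt", "replicate"}
    missing = required - set(displaced.columns)
    if missing:
        raise SchemaError(f"displaced table missing columns: {sorted(missing)}")
    if displaced.empty:
        empty = pd.DataFrame(columns=FLOW_COLUMNS)
        return empty, couple(empty, factors)
    unknown = sorted(set(displaced["substitute"].unique()) - set(specs))
    if unknown:
        raise MissingKeyError(f"no substitution spec for: {unknown}")
    rows = []
    for sub_id, grp in displaced.groupby("substitute", sort=False):
        spec = specs[str(sub_id)]
        flows = grp.rename(columns={"substitute": "material"}).copy()
        flows["mass_mt"] = flows["displaced_mass_mt"] * spec.ratio
        flows["stage"] = spec.stage_id
        rows.append(flows[FLOW_COLUMNS])
    sub_flows = pd.concat(rows, ignore_index=True)
    sub_flows = sub_flows.loc[sub_flows["mass_mt"] > 0].reset_index(drop=True)
    return sub_flows, couple(sub_flows, factors)


def build_ledger(
    flows: pd.DataFrame,
    factors: FactorTable,
    credit_rules: tuple[CreditRule, ...] | list[CreditRule] = (),
    substitution_specs: dict[str, SubstitutionSpec] | None = None,
    displaced: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full coupling chain: induced records + credits + substitute records."""
    ledger = couple(flows, factors)
    if credit_rules:
        ledger = apply_credits(ledger, flows, credit_rules, factors)
    if displaced is not None and len(displaced) and substitution_specs:
        _, sub_ledger = apply_substitution(displaced, substitution_specs, factors)
        ledger = pd.concat([ledger, sub_ledger], ignore_index=True)
    return ledger


class ScenarioResult:
    """Aggregated DALY ledger with closure-checked breakdowns.

    ``totals`` holds net, induced and avoided DALYs per (scenario, year) —
    the dual reporting convention in which per-process charts show induced
    and avoided effects separately while net totals sum them.
    """

    def __init__(self, ledger: pd.DataFrame, substance_factors: pd.DataFrame | None = None):
        required = set(KEY_COLUMNS) | {"dalys", "direction", "source_stage"} | set(DALY_COLUMNS)
        missing = required - set(ledger.columns)
        if missing:
            raise SchemaError(f"ledger missing columns: {sorted(missing)}")
        self.ledger = ledger.reset_index(drop=True)
        self.substance_factors = substance_factors
        grouped = self.ledger.groupby(["scenario", "year"])
        net = grouped["dalys"].sum()
        induced = (
            self.ledger.loc[self.ledger["direction"] == DIRECTION_INDUCED]
            .groupby(["scenario", "year"])["dalys"]
            .sum()
        )
        self.totals = pd.DataFrame({"net": net}).assign(
            induced=induced.reindex(net.index, fill_value=0.0)
        )
        self.totals["avoided"] = self.totals["net"] - self.totals["induced"]
        self.cumulative = self.totals["net"].groupby("scenario").sum()
        self._check_closure()

    def _check_closure(self, rtol: float = 1e-9) -> None:
        net = float(self.ledger["dalys"].sum())
        scale = max(1.0, abs(net))
        mid_sum = float(self.ledger[DALY_COLUMNS].to_numpy().sum())
        if abs(mid_sum - net) > rtol * scale:
            raise SchemaError(
                f"midpoint closure violated: {mid_sum} vs net {net}"
            )
        for dim in ["scenario", "archetype", "material", "stage", "direction"]:
            s = float(self.ledger.groupby(dim)["dalys"].sum().sum())
            if abs(s - net) > rtol * scale:
                raise SchemaError(f"{dim} closure violated: {s} vs net {net}")

    # -- accessors ---------------------------------------------------------

    def _slice(self, scenario=None, year=None, replicate=None) -> pd.DataFrame:
        df = self.ledger
        if scenario is not None:
            df = df.loc[df["scenario"] == scenario]
        if year is not None:
            df = df.loc[df["year"] == year]
        if replicate is not None:
            df = df.loc[df["replicate"] == replicate]
        return df

    def total(self, scenario: str, year: int | None = None, replicate=POINT_REPLICATE) -> float:
        """Net DALYs for a scenario-year (or the whole window)."""
        return float(self._slice(scenario, year, replicate)["dalys"].sum())

    def induced_total(self, scenario: str, year: int | None = None, replicate=POINT_REPLICATE) -> float:
        """Credits-excluded total: induced records only."""
        df = self._slice(scenario, year, replicate)
        return float(df.loc[df["direction"] == DIRECTION_INDUCED, "dalys"].sum())

    def annual_series(self, scenario: str, replicate=POINT_REPLICATE) -> pd.Series:
        df = self._slice(scenario, replicate=replicate)
        return df.groupby("year")["dalys"].sum()

    def breakdown(
        self,
        dimension: str,
        scenario: str | None = None,
        year: int | None = None,
        replicate=POINT_REPLICATE,
    ) -> pd.Series:
        """Net DALYs grouped along one dimension (sums to the net total)."""
        df = self._slice(scenario, year, replicate)
        if dimension == "midpoint":
            s = df[DALY_COLUMNS].sum()
            s.index = [c.removeprefix("daly_") for c in s.index]
            return s
        if dimension == "substance":
            return self._substance_breakdown(df)
        if dimension in ("stage", "archetype", "material", "direction", "source_stage"):
            return df.groupby(dimension)["dalys"].sum()
        raise SchemaError(f"unknown breakdown dimension {dimension!r}")

    def _substance_breakdown(self, df: pd.DataFrame) -> pd.Series:
        if self.substance_factors is None:
            raise SchemaError(
                "substance breakdown requires per-substance unit factors"
            )
        merged = df.merge(
            self.substance_factors.rename(
                columns={
                    "material_id": "material",
                    "stage_id": "stage",
                    "archetype_id": "archetype",
                }
            ),
            on=["material", "stage", "archetype"],
            how="inner",
        )
        merged["sub_dalys"] = merged["mass_mt"] * merged["dalys_per_unit"]
        return merged.groupby("substance_id")["sub_dalys"].sum()


def aggregate(
    ledger: pd.DataFrame, substance_factors: pd.DataFrame | None = None
) -> ScenarioResult:
    """Wrap a DALY ledger in a closure-checked ScenarioResult."""
    return ScenarioResult(ledger, substance_factors=substance_factors)


def percent_reduction(
    result: ScenarioResult,
    reference_scenario: str,
    target_scenario: str,
    window: tuple[int, int] = (2016, 2040),
) -> dict[str, float]:
    """Percent reduction of the target's cumulative burden vs the reference.

    Computed on unrounded totals over the window; the two totals are
    returned alongside so reports can print them at two significant
    figures.
    """
    lo, hi = window
    df = result.ledger.loc[
        (result.ledger["year"] >= lo)
        & (result.ledger["year"] <= hi)
        & (result.ledger["replicate"] == POINT_REPLICATE)
    ]
    by_scen = df.groupby("scenario")["dalys"].sum()
    for scen in (reference_scenario, target_scenario):
        if scen not in by_scen.index:
            raise MissingKeyError(f"scenario {scen!r} absent over {window}")
    ref = float(by_scen[reference_scenario])
    tgt = float(by_scen[target_scenario])
    if ref == 0.0:
        raise SchemaError("reference total is zero; reduction undefined")
    return {
        "percent": 100.0 * (ref - tgt) / ref,
        "reference_total": ref,
        "target_total": tgt,
    }


def contribution_analysis(
    result: ScenarioResult,
    dimension: str,
    threshold: float = 0.0,
    scenario: str | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """Ranked shares of the net total along one dimension.

    Shares are percentages of the net total, sorted descending; entries
    with |share| below ``threshold`` (in percent) pool into ``other``.
    Shares sum to 100 by construction.
    """
    values = result.breakdown(dimension, scenario=scenario, year=year)
    total = float(values.sum())
    if total == 0.0:
        raise SchemaError("net total is zero; contribution shares undefined")
    shares = 100.0 * values / total
    keep = shares[np.abs(shares) >= threshold].sort_values(ascending=False)
    pooled = float(shares.sum() - keep.sum())
    out = keep.rename("share_pct").to_frame()
    out["dalys"] = values.reindex(keep.index)
    if abs(pooled) > 0 or len(keep) < len(shares):
        other = pd.DataFrame(
            {"share_pct": [pooled], "dalys": [total * pooled / 100.0]},
            index=pd.Index(["other"], name=out.index.name),
        )
        out = pd.concat([out, other])
    out.index.name = dimension
    return out


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------


def write_flows_csv(flows: pd.DataFrame, path) -> None:
    _validate_flows(flows)[FLOW_COLUMNS].to_csv(path, index=False)


def read_flows_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a flow table, optionally renaming columns via ``column_map``.

    ``column_map`` maps source column names to the canonical schema —
    the hook for importing externally deposited flow datasets.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "replicate" not in df.columns:
        df["replicate"] = POINT_REPLICATE
    df["replicate"] = df["replicate"].astype(str)
    unknown_scen = set(df.get("scenario", pd.Series(dtype=object)).unique()) - set(SCENARIOS)
    if unknown_scen:
        raise SchemaError(f"unknown scenario ids in flow file: {sorted(unknown_scen)}")
    return _validate_flows(df)[FLOW_COLUMNS]
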