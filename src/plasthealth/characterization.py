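"""Impact assessment: elementary flows -> health midpoints -> DALYs.

Midpoint characterization multiplies each substance emission by a
substance/compartment-specific factor expressed in the midpoint's reference
unit per kg (e.g. kg CO2-eq for global warming).  Endpoint conversion then
maps each midpoint total to disability-adjusted life-years through a single
DALY-per-reference-unit factor (hierarchic perspective, 100-year horizon).
Characterization is linear, so avoided-burden credits pass through as
negative values; a *negative endpoint factor*, by contrast, is rejected as
a data error.

Uncharacterized substances are never silently dropped: they are reported
through a logged warning carrying the substance id and emitted mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .constants import MIDPOINTS
from .exceptions import SchemaError

__all__ = [
    "CharacterizationTable",
    "MidpointVector",
    "characterize",
    "total_dalys",
    "read_characterization_csv",
    "write_characterization_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MidpointVector:
    """Characterized impacts: midpoint reference units and their DALYs."""

    values: dict[str, float] = field(default_factory=dict)
    daly_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in set(self.values) | set(self.daly_values):
            if key not in MIDPOINTS:
                raise SchemaError(f"unknown midpoint id {key!r}")
        for d in (self.values, self.daly_values):
            for key, v in d.items():
                if not math.isfinite(v):
                    raise SchemaError(f"non-finite value for midpoint {key!r}")

    def __add__(self, other: "MidpointVector") -> "MidpointVector":
        return MidpointVector(
            values={
                m: self.values.get(m, 0.0) + other.values.get(m, 0.0)
                for m in MIDPOINTS
            },
            daly_values={
                m: self.daly_values.get(m, 0.0) + other.daly_values.get(m, 0.0)
                for m in MIDPOINTS
            },
        )

    def scaled(self, factor: float) -> "MidpointVector":
        return MidpointVector(
            values={m: v * factor for m, v in self.values.items()},
            daly_values={m: v * factor for m, v in self.daly_values.items()},
        )

    @classmethod
    def zeros(cls) -> "MidpointVector":
        return cls(
            values={m: 0.0 for m in MIDPOINTS},
            daly_values={m: 0.0 for m in MIDPOINTS},
        )


@dataclass(frozen=True)
class CharacterizationTable:
    """Substance -> midpoint and midpoint -> DALY conversion factors.

    ``midpoint_factors`` maps (substance_id, compartment, midpoint_id) to a
    factor in the midpoint's reference unit per kg emitted;
    ``endpoint_factors`` maps midpoint_id to DALYs per reference unit.
    """

    midpoint_factors: dict[tuple[str, str, str], float]
    endpoint_factors: dict[str, float]
    perspective: str = "hierarchic"
    time_horizon_years: int = 100

    def __post_init__(self) -> None:
        for (sub, comp, mid), factor in self.midpoint_factors.items():
            if mid not in MIDPOINTS:
                raise SchemaError(f"unknown midpoint {mid!r} for substance {sub!r}")
            if not math.isfinite(factor):
                raise SchemaError(f"non-finite factor for ({sub!r}, {comp!r}, {mid!r})")
        for mid, factor in self.endpoint_factors.items():
            if mid not in MIDPOINTS:
                raise SchemaError(f"unknown midpoint {mid!r} in endpoint factors")
            if not math.isfinite(factor):
                raise SchemaError(f"non-finite endpoint factor for {mid!r}")
            if factor < 0:
                raise SchemaError(
                    f"negative endpoint factor {factor} for midpoint {mid!r}"
                )

    def covered_substances(self) -> set[str]:
        return {sub for sub, _, _ in self.midpoint_factors}

    def with_midpoint_factors(
        self, replacement: dict[tuple[str, str, str], float], midpoint: str
    ) -> "CharacterizationTable":
        """Swap out one midpoint's sub-table (e.g. an alternative GWP set)."""
        kept = {
            k: v for k, v in self.midpoint_factors.items() if k[2] != midpoint
        }
        for key in replacement:
            if key[2] != midpoint:
                raise SchemaError(
                    f"replacement factor {key} targets a different midpoint"
                )
        kept.update(replacement)
        return CharacterizationTable(
            midpoint_factors=kept,
            endpoint_factors=dict(self.endpoint_factors),
            perspective=self.perspective,
            time_horizon_years=self.time_horizon_years,
        )


def characterize(
    g: pd.Series, table: CharacterizationTable
) -> MidpointVector:
    """Characterize an elementary-flow vector to the eight health midpoints.

    ``g`` is indexed by (substance, compartment, term); the short/long term
    split does not affect factors and is summed over here.  Substances with
    no factor for any midpoint are reported via ``logger.warning`` with
    their total emitted mass.
    """
    values = {m: 0.0 for m in MIDPOINTS}
    uncovered: dict[str, float] = {}
    covered = table.covered_substances()
    for key, amount in g.items():
        sub, comp, _term = key
        if sub not in covered:
            uncovered[sub] = uncovered.get(sub, 0.0) + float(amount)
            continue
        for mid in MIDPOINTS:
            factor = table.midpoint_factors.get((sub, comp, mid))
            if factor is not None:
                values[mid] += factor * float(amount)
    for sub, mass in sorted(uncovered.items()):
        logger.warning(
            "substance %r has no characterization factor; %g kg uncharacterized",
            sub,
            mass,
        )
    daly_values = {
        m: values[m] * table.endpoint_factors.get(m, 0.0) for m in MIDPOINTS
    }
    return MidpointVector(values=values, daly_values=daly_values)


def total_dalys(mv: MidpointVector) -> tuple[float, dict[str, float]]:
    """Total DALYs and the unrounded per-midpoint breakdown.

    The total is the exact sum of the breakdown (closure by construction,
    asserted here).
    """
    breakdown = {m: mv.daly_values.get(m, 0.0) for m in MIDPOINTS}
    total = sum(breakdown.values())
    assert total == sum(breakdown.values())  # closure
    return total, breakdown


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------


def write_characterization_csv(
    table: CharacterizationTable, midpoint_path, endpoint_path
) -> None:
    mrows = [
        (sub, comp, mid, factor)
        for (sub, comp, mid), factor in sorted(table.midpoint_factors.items())
    ]
    pd.DataFrame(
        mrows, columns=["substance_id", "compartment", "midpoint_id", "factor"]
    ).to_csv(midpoint_path, index=False)
    erows = sorted(table.endpoint_factors.items())
    pd.DataFrame(erows, columns=["midpoint_id", "dalys_per_unit"]).to_csv(
        endpoint_path, index=False
    )


def read_characterization_csv(
    midpoint_path, endpoint_path, perspective: str = "hierarchic",
    time_horizon_years: int = 100,
) -> CharacterizationTable:
    mdf = pd.read_csv(midpoint_path)
    required = {"substance_id", "compartment", "midpoint_id", "factor"}
    if not required <= set(mdf.columns):
        raise SchemaError(
            f"midpoint factor CSV missing columns: {sorted(required - set(mdf.columns))}"
        )
    edf = pd.read_csv(endpoint_path)
    if not {"midpoint_id", "dalys_per_unit"} <= set(edf.columns):
        raise SchemaError("endpoint factor CSV needs midpoint_id, dalys_per_unit")
    return CharacterizationTable(
        midpoint_factors={
            (str(r.substance_id), str(r.compartment), str(r.midpoint_id)): float(
                r.factor
            )
            for r in mdf.itertuples()
        },
        endpoint_factors={
            str(r.midpoint_id): float(r.dalys_per_unit) for r in edf.itertuples()
        },
        perspective=perspective,
        time_horizon_years=time_horizon_years,
    )
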