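"""Uncertainty propagation and sensitivity sweeps.

Flow-level uncertainty arrives as Monte Carlo replicates of the mass-flow
dataset (300 replicate simulations per scenario by default).  The full
coupling pipeline runs per replicate and DALY totals are summarized as the
arithmetic mean with empirical percentile intervals (2.5/97.5 at the
default 95% level) — the interval method is recorded in the output.

The substitution-ratio sweep re-evaluates the pipeline at the documented
ratio-range endpoints (0.4-9.0 for paper-based substitutes, 0.8-1.4 for
compostables) and reports the resulting DALY range per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .blocks import FactorTable
from .coupling import (
    POINT_REPLICATE,
    CreditRule,
    SubstitutionSpec,
    build_ledger,
)
from .exceptions import SchemaError

__all__ = [
    "IntervalEstimate",
    "ReplicateSet",
    "mc_summary",
    "substitution_sensitivity",
    "INTERVAL_METHOD",
]

INTERVAL_METHOD = "empirical percentile"


@dataclass(frozen=True)
class IntervalEstimate:
    """Mean and percentile interval of a DALY total."""

    mean: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.lower <= self.mean <= self.upper:
            raise SchemaError(
                f"interval bounds out of order: {self.lower} <= {self.mean} "
                f"<= {self.upper} fails"
            )
        if not 0 < self.level < 1:
            raise SchemaError(f"level must be in (0, 1), got {self.level}")


class ReplicateSet:
    """Replicated mass-flow datasets.

    Wraps either a flow table whose ``replicate`` column indexes draws, or
    a lazy generator of ``(replicate_id, flows, displaced)`` triples (used
    for synthetic worlds so the full replicate stack never materializes at
    once).
    """

    def __init__(self, source: Iterable | pd.DataFrame, displaced: pd.DataFrame | None = None):
        self._source = source
        self._displaced = displaced

    @classmethod
    def from_dataframe(
        cls, flows: pd.DataFrame, displaced: pd.DataFrame | None = None
    ) -> "ReplicateSet":
        rids = sorted(set(flows["replicate"].unique()) - {POINT_REPLICATE})
        if len(rids) < 2:
            raise SchemaError(
                f"need at least 2 replicates for interval estimation, got {len(rids)}"
            )
        return cls(flows, displaced)

    def __iter__(self) -> Iterator[tuple[str, pd.DataFrame, pd.DataFrame | None]]:
        if isinstance(self._source, pd.DataFrame):
            flows = self._source
            rids = sorted(set(flows["replicate"].unique()) - {POINT_REPLICATE})
            for rid in rids:
                f = flows.loc[flows["replicate"] == rid]
                d = None
                if self._displaced is not None:
                    d = self._displaced.loc[self._displaced["replicate"] == rid]
                yield str(rid), f, d
        else:
            yield from self._source


def mc_summary(
    replicates: ReplicateSet,
    factors: FactorTable,
    credit_rules: tuple[CreditRule, ...] = (),
    substitution_specs: dict[str, SubstitutionSpec] | None = None,
    level: float = 0.95,
    by: tuple[str, ...] = ("scenario", "year"),
) -> pd.DataFrame:
    """Percentile confidence intervals of DALY totals across replicates.

    Runs the full coupling per replicate and summarizes totals grouped by
    ``by`` (default: per scenario-year).  Deterministic given the replicate
    inputs; invariant to replicate ordering by construction (percentiles
    are order statistics).

    Raises
    ------
    SchemaError
        On fewer than 2 replicates or inconsistent flow keys across them.
    """
    if not 0 < level < 1:
        raise SchemaError(f"level must be in (0, 1), got {level}")
    key_cols = ["year", "scenario", "archetype", "material", "stage"]
    totals: list[pd.Series] = []
    rids: list[str] = []
    ref_keys: frozenset | None = None
    for rid, flows, displaced in replicates:
        keys = frozenset(map(tuple, flows[key_cols].itertuples(index=False)))
        if ref_keys is None:
            ref_keys = keys
        elif keys != ref_keys:
            raise SchemaError(
                f"replicate {rid!r} has a different flow-key structure "
                f"({len(keys)} vs {len(ref_keys)} keys)"
            )
        ledger = build_ledger(
            flows, factors, credit_rules, substitution_specs, displaced
        )
        totals.append(ledger.groupby(list(by))["dalys"].sum().rename(rid))
        rids.append(rid)
    if len(totals) < 2:
        raise SchemaError(
            f"need at least 2 replicates for interval estimation, got {len(totals)}"
        )
    stack = pd.concat(totals, axis=1)
    if stack.isna().any().any():
        raise SchemaError("replicates disagree on the grouped keys")
    alpha = (1.0 - level) / 2.0
    values = stack.to_numpy()
    out = pd.DataFrame(
        {
            "mean": values.mean(axis=1),
            "lower": np.quantile(values, alpha, axis=1),
            "upper": np.quantile(values, 1.0 - alpha, axis=1),
        },
        index=stack.index,
    )
    out["level"] = level
    out["n"] = len(rids)
    out["method"] = INTERVAL_METHOD
    return out.reset_index()


def substitution_sensitivity(
    flows: pd.DataFrame,
    displaced: pd.DataFrame,
    factors: FactorTable,
    specs: dict[str, SubstitutionSpec],
    year: int,
    credit_rules: tuple[CreditRule, ...] = (),
    grid_points: int = 2,
) -> pd.DataFrame:
    """DALY range per scenario across the substitution-ratio ranges.

    Evaluates the full pipeline with every ranged substitute set jointly to
    the low endpoint, then jointly to the high endpoint (optionally on a
    ``grid_points``-point grid between them), for the requested year.
    Returns per-scenario totals at each evaluation plus the (min, max)
    envelope and which endpoint drives the maximum.
    """
    if not specs:
        raise SchemaError("empty substitution-spec list")
    if grid_points < 2:
        raise SchemaError(f"grid must have >= 2 points, got {grid_points}")
    lo, hi = int(flows["year"].min()), int(flows["year"].max())
    if not lo <= year <= hi:
        raise SchemaError(f"year {year} outside flow window [{lo}, {hi}]")

    fy = flows.loc[
        (flows["year"] == year) & (flows["replicate"] == POINT_REPLICATE)
    ]
    dy = displaced.loc[
        (displaced["year"] == year) & (displaced["replicate"] == POINT_REPLICATE)
    ]

    def variant(t: float) -> dict[str, SubstitutionSpec]:
        out = {}
        for sid, spec in specs.items():
            if spec.ratio_range is None:
                out[sid] = spec
            else:
                low, high = spec.ratio_range
                out[sid] = spec.with_ratio(low + t * (high - low))
        return out

    grid = np.linspace(0.0, 1.0, grid_points)
    evals = []
    for t in grid:
        ledger = build_ledger(fy, factors, credit_rules, variant(float(t)), dy)
        totals = ledger.groupby("scenario")["dalys"].sum().rename(f"t={t:.2f}")
        evals.append((float(t), totals))
    stack = pd.concat([s for _, s in evals], axis=1)
    ts = [t for t, _ in evals]
    arr = stack.to_numpy()
    out = pd.DataFrame(
        {
            "total_low": arr[:, 0],
            "total_high": arr[:, -1],
            "min": arr.min(axis=1),
            "max": arr.max(axis=1),
        },
        index=stack.index,
    )
    out["driving_endpoint"] = [
        "high" if ts[j] > 0.5 else "low" for j in arr.argmax(axis=1)
    ]
    out["year"] = year
    return out.reset_index()
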