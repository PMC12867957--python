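"""Model and results objects for scenario health-burden estimation.

`ScenarioBurdenModel` bundles the data of one analysis — annual mass flows,
the unit-factor building blocks, avoided-burden credit rules and
substitution specs — and `fit()` executes the coupling pipeline, returning
a `ScenarioBurdenResults` with totals, breakdowns, Monte Carlo intervals
and a printable summary.

    >>> model = ScenarioBurdenModel.from_synthetic_world(seed=1)
    >>> res = model.fit(n_replicates=50)
    >>> print(res.summary())
"""

from __future__ import annotations

import pandas as pd

from .blocks import FactorTable
from .coupling import (
    POINT_REPLICATE,
    CreditRule,
    ScenarioResult,
    SubstitutionSpec,
    aggregate,
    build_ledger,
    contribution_analysis,
    percent_reduction,
    read_flows_csv,
)
from .exceptions import SchemaError
from .reporting import format_daly, round_sig
from .uncertainty import (
    INTERVAL_METHOD,
    ReplicateSet,
    mc_summary,
    substitution_sensitivity,
)

__all__ = ["ScenarioBurdenModel", "ScenarioBurdenResults"]


class ScenarioBurdenModel:
    """Health-burden model for mass-flow scenarios.

    Parameters
    ----------
    flows : DataFrame
        Mass flows in the canonical schema (year, scenario, archetype,
        material, stage, mass_mt, replicate).  Rows with ``replicate ==
        "point"`` form the point estimate; other replicate ids feed the
        Monte Carlo summary.
    factors : FactorTable
        Unit impact factors (DALYs per Mt / per service-year).
    credit_rules : sequence of CreditRule, optional
        Avoided-burden bookings for recycling and waste-to-fuel.
    substitution_specs : mapping, optional
        Substitute conversion ratios; required when ``displaced`` is given.
    displaced : DataFrame, optional
        Displaced plastics masses to expand into substitute flows.
    """

    def __init__(
        self,
        flows: pd.DataFrame,
        factors: FactorTable,
        credit_rules: tuple[CreditRule, ...] = (),
        substitution_specs: dict[str, SubstitutionSpec] | None = None,
        displaced: pd.DataFrame | None = None,
        substance_factors: pd.DataFrame | None = None,
    ):
        self.flows = flows
        self.factors = factors
        self.credit_rules = tuple(credit_rules)
        self.substitution_specs = substitution_specs
        self.displaced = displaced
        self.substance_factors = substance_factors
        self.world = None  # set by from_synthetic_world

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_synthetic_world(
        cls, config=None, seed: int = 0
    ) -> "ScenarioBurdenModel":
        """Build model and data from the synthetic-world generator."""
        from .synthetic import WorldConfig, gen_flows, gen_world

        if config is None:
            config = WorldConfig(seed=seed)
        world = gen_world(config)
        flows, displaced = gen_flows(config)
        model = cls(
            flows,
            world.factor_table,
            credit_rules=world.credit_rules,
            substitution_specs=world.substitution_specs,
            displaced=displaced,
        )
        model.world = world
        return model

    @classmethod
    def from_csv(
        cls,
        flows_path,
        factors_path,
        displaced_path=None,
        column_map: dict[str, str] | None = None,
        credit_rules: tuple[CreditRule, ...] = (),
        substitution_specs: dict[str, SubstitutionSpec] | None = None,
    ) -> "ScenarioBurdenModel":
        """Load flows and factors from CSV (the external-data entry point)."""
        flows = read_flows_csv(flows_path, column_map=column_map)
        factors = FactorTable.read_csv(factors_path)
        displaced = None
        if displaced_path is not None:
            displaced = pd.read_csv(displaced_path)
            if "replicate" not in displaced.columns:
                displaced["replicate"] = POINT_REPLICATE
        return cls(
            flows,
            factors,
            credit_rules=credit_rules,
            substitution_specs=substitution_specs,
            displaced=displaced,
        )

    # -- estimation --------------------------------------------------------

    def _point(self, df: pd.DataFrame | None) -> pd.DataFrame | None:
        if df is None:
            return None
        return df.loc[df["replicate"] == POINT_REPLICATE]

    def fit(
        self, n_replicates: int | None = None, ci_level: float = 0.95
    ) -> "ScenarioBurdenResults":
        """Run the coupling pipeline; optionally add Monte Carlo intervals.

        ``n_replicates`` controls the Monte Carlo summary: ``None`` uses
        replicates already present in the flow table (if any); a positive
        number generates that many synthetic replicates (only for models
        built from a synthetic world); ``0`` skips uncertainty.
        """
        point_flows = self._point(self.flows)
        ledger = build_ledger(
            point_flows,
            self.factors,
            self.credit_rules,
            self.substitution_specs,
            self._point(self.displaced),
        )
        result = aggregate(ledger, substance_factors=self.substance_factors)

        intervals = None
        replicates = self._replicate_source(n_replicates)
        if replicates is not None:
            intervals = mc_summary(
                replicates,
                self.factors,
                self.credit_rules,
                self.substitution_specs,
                level=ci_level,
            )
        return ScenarioBurdenResults(self, result, intervals, ci_level)

    def _replicate_source(self, n_replicates: int | None):
        if n_replicates == 0:
            return None
        has_reps = (self.flows["replicate"] != POINT_REPLICATE).any()
        if has_reps:
            return ReplicateSet.from_dataframe(self.flows, self.displaced)
        if n_replicates is None:
            return None
        if self.world is None:
            raise SchemaError(
                "flow table has no replicates and the model was not built "
                "from a synthetic world; cannot generate them"
            )
        from .synthetic import gen_replicates

        return ReplicateSet(
            gen_replicates(
                self.world.config,
                self._point(self.flows),
                self._point(self.displaced),
                n_replicates=n_replicates,
            )
        )


class ScenarioBurdenResults:
    """Fitted scenario burdens: estimates, intervals, diagnostics.

    Attributes
    ----------
    result : ScenarioResult
        The closure-checked DALY ledger and its aggregations.
    intervals : DataFrame or None
        Monte Carlo mean/lower/upper per scenario-year.
    """

    def __init__(
        self,
        model: ScenarioBurdenModel,
        result: ScenarioResult,
        intervals: pd.DataFrame | None,
        ci_level: float,
    ):
        self.model = model
        self.result = result
        self.intervals = intervals
        self.ci_level = ci_level

    # -- convenience accessors --------------------------------------------

    @property
    def totals(self) -> pd.DataFrame:
        return self.result.totals

    @property
    def cumulative(self) -> pd.Series:
        return self.result.cumulative

    def total(self, scenario: str, year: int | None = None) -> float:
        return self.result.total(scenario, year)

    def percent_reduction(
        self, reference: str, target: str, window: tuple[int, int] | None = None
    ) -> dict[str, float]:
        years = self.result.ledger["year"]
        window = window or (int(years.min()), int(years.max()))
        return percent_reduction(self.result, reference, target, window)

    def contributions(
        self, dimension: str, threshold: float = 0.0, scenario=None, year=None
    ) -> pd.DataFrame:
        return contribution_analysis(
            self.result, dimension, threshold, scenario=scenario, year=year
        )

    def sensitivity(self, year: int, grid_points: int = 2) -> pd.DataFrame:
        if self.model.substitution_specs is None or self.model.displaced is None:
            raise SchemaError("model has no substitution specs / displaced flows")
        return substitution_sensitivity(
            self.model._point(self.model.flows),
            self.model._point(self.model.displaced),
            self.model.factors,
            self.model.substitution_specs,
            year,
            credit_rules=self.model.credit_rules,
            grid_points=grid_points,
        )

    def interval(self, scenario: str, year: int):
        from .uncertainty import IntervalEstimate

        if self.intervals is None:
            raise SchemaError("no Monte Carlo intervals were computed")
        sel = self.intervals.loc[
            (self.intervals["scenario"] == scenario)
            & (self.intervals["year"] == year)
        ]
        if sel.empty:
            raise SchemaError(f"no interval for ({scenario!r}, {year})")
        row = sel.iloc[0]
        return IntervalEstimate(
            mean=float(row["mean"]),
            lower=float(row["lower"]),
            upper=float(row["upper"]),
            level=float(row["level"]),
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Printable scenario comparison (two-significant-figure values)."""
        from .constants import SCENARIOS

        ledger = self.result.ledger
        y0, y1 = int(ledger["year"].min()), int(ledger["year"].max())
        present = set(ledger["scenario"])
        scenarios = [s for s in SCENARIOS if s in present] + sorted(
            present - set(SCENARIOS)
        )
        ref = scenarios[0]
        lines = [
            "Scenario health-burden results (DALYs)",
            "=" * 78,
            f"window: {y0}-{y1}    scenarios: {len(scenarios)}    "
            f"ledger records: {len(ledger)}",
        ]
        if self.intervals is not None:
            n = int(self.intervals["n"].iloc[0])
            lines.append(
                f"uncertainty: {INTERVAL_METHOD}, {n} replicates, "
                f"{self.ci_level:.0%} level"
            )
        lines.append("-" * 78)
        header = (
            f"{'scenario':<22}{f'{y0}':>10}{f'{y1}':>10}{'cumulative':>13}"
            f"{'vs ' + ref:>10}"
        )
        lines.append(header)
        lines.append("-" * 78)
        for scen in scenarios:
            first = self.total(scen, y0)
            last = self.total(scen, y1)
            cum = float(self.cumulative[scen])
            try:
                red = self.percent_reduction(ref, scen)["percent"]
            except SchemaError:
                red = float("nan")
            lines.append(
                f"{scen:<22}{round_sig(first):>10.3g}{round_sig(last):>10.3g}"
                f"{round_sig(cum):>13.3g}{round_sig(red):>9.3g}%"
            )
        lines.append("-" * 78)
        if self.intervals is not None:
            for scen in scenarios:
                try:
                    iv = self.interval(scen, y1)
                except SchemaError:
                    continue
                lines.append(
                    f"{scen:<22}{y1} total {format_daly(iv.mean)} "
                    f"({self.ci_level:.0%} CI {format_daly(iv.lower)}"
                    f"-{format_daly(iv.upper)})"
                )
            lines.append("-" * 78)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_annual_totals(self, ax=None):
        from .plotting import plot_annual_totals

        return plot_annual_totals(self.result, intervals=self.intervals, ax=ax)

    def plot_contributions(self, dimension: str, scenario: str, year: int, ax=None):
        from .plotting import plot_contributions

        return plot_contributions(
            self.result, dimension, scenario=scenario, year=year, ax=ax
        )
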