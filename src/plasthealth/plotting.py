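"""Matplotlib figure helpers mirroring the standard reporting charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .constants import SCENARIOS
from .coupling import ScenarioResult, contribution_analysis

__all__ = ["plot_annual_totals", "plot_contributions", "plot_midpoint_stack"]


def plot_annual_totals(result: ScenarioResult, intervals=None, ax=None):
    """Annual net DALYs per scenario over the modelled window."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    present = [s for s in SCENARIOS if s in set(result.ledger["scenario"])]
    for scen in present:
        series = result.annual_series(scen)
        ax.plot(series.index, series.values / 1e6, label=scen)
        if intervals is not None:
            sel = intervals.loc[intervals["scenario"] == scen].sort_values("year")
            if not sel.empty:
                ax.fill_between(
                    sel["year"], sel["lower"] / 1e6, sel["upper"] / 1e6, alpha=0.2
                )
    ax.set_xlabel("year")
    ax.set_ylabel("DALYs (million)")
    ax.legend(fontsize=8)
    return ax


def plot_contributions(
    result: ScenarioResult, dimension: str, scenario: str, year: int,
    threshold: float = 1.0, ax=None,
):
    """Horizontal bar chart of contribution shares along one dimension."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    shares = contribution_analysis(
        result, dimension, threshold=threshold, scenario=scenario, year=year
    )
    ax.barh(shares.index.astype(str), shares["share_pct"])
    ax.set_xlabel(f"share of net DALYs (%), {scenario} {year}")
    ax.invert_yaxis()
    return ax


def plot_midpoint_stack(result: ScenarioResult, year: int, ax=None):
    """Stacked midpoint DALYs per scenario for one year."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    present = [s for s in SCENARIOS if s in set(result.ledger["scenario"])]
    bottoms = [0.0] * len(present)
    mids = result.breakdown("midpoint").index
    for mid in mids:
        vals = [
            result.breakdown("midpoint", scenario=s, year=year).get(mid, 0.0) / 1e6
            for s in present
        ]
        ax.bar(present, vals, bottom=bottoms, label=mid)
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_ylabel(f"DALYs (million), {year}")
    ax.tick_params(axis="x", rotation=30)
    ax.legend(fontsize=7)
    return ax
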