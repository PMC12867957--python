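"""Reporting conventions: rounding, summary tables, run manifests.

Printed values follow the two-significant-figure convention; all internal
arithmetic stays unrounded, so row totals and inter-column differences in
printed tables can show minor rounding discrepancies.
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .constants import MIDPOINTS, SCENARIOS

__all__ = [
    "round_sig",
    "format_daly",
    "midpoint_table",
    "reductions_table",
    "write_manifest",
    "file_sha256",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_daly(x: float, sig: int = 2) -> str:
    """Human-readable DALY count at two significant figures."""
    r = round_sig(x, sig)
    if abs(r) >= 1e6:
        return f"{r / 1e6:g} million"
    if abs(r) >= 1e3:
        return f"{r / 1e3:g} thousand"
    return f"{r:g}"


def midpoint_table(result, year: int, sig: int = 2) -> pd.DataFrame:
    """Wide table: midpoint rows x scenario columns for one year.

    Values in thousands of DALYs, rounded to ``sig`` significant figures;
    a Total row sums the unrounded values before rounding.
    """
    cols = {}
    scenarios = [s for s in SCENARIOS if s in set(result.ledger["scenario"])]
    for scen in scenarios:
        bd = result.breakdown("midpoint", scenario=scen, year=year)
        col = {m: bd.get(m, 0.0) for m in MIDPOINTS}
        col["total"] = sum(col.values())
        cols[scen] = col
    df = pd.DataFrame(cols)
    return df.map(lambda v: round_sig(v / 1e3, sig))


def reductions_table(result, window: tuple[int, int] = (2016, 2040)) -> pd.DataFrame:
    """Cumulative totals and percent reduction vs the first scenario.

    Columns follow the canonical scenario order; percentages computed on
    unrounded totals, printed at two significant figures.
    """
    from .coupling import percent_reduction
    from .exceptions import SchemaError

    scenarios = [s for s in SCENARIOS if s in set(result.ledger["scenario"])]
    ref = scenarios[0]
    rows = []
    for scen in scenarios:
        try:
            red = percent_reduction(result, ref, scen, window=window)
            pct = round_sig(red["percent"])
            total = red["target_total"]
        except SchemaError:  # zero reference burden: reduction undefined
            pct = float("nan")
            total = float(result.cumulative.get(scen, 0.0))
        rows.append(
            {
                "scenario": scen,
                "cumulative_dalys": total,
                "cumulative_dalys_2sf": round_sig(total),
                "reduction_vs_reference_pct": pct,
            }
        )
    return pd.DataFrame(rows)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    *,
    seed: int | None,
    config: dict | None = None,
    inputs: dict[str, str] | None = None,
    interval_method: str | None = None,
) -> dict:
    """Record what produced a result bundle: config, seed, input hashes."""
    from . import __version__

    manifest = {
        "software": "plasthealth",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "rounding_convention": "two significant figures for printed values",
        "interval_method": interval_method,
        "config": config,
        "input_hashes": {
            name: file_sha256(p) for name, p in (inputs or {}).items()
            if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
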