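"""Matrix-based lifecycle-inventory engine.

A product system is a set of unit processes exchanging flows: each process
declares technosphere inputs (amounts of other processes required per unit
of its own output) and elementary emissions (substance releases to an
environmental compartment, labelled short- or long-term).  Total elementary
emissions g for a functional-unit demand f follow the standard linear
inventory model

    g = B (I - A)^-1 f

with A the technosphere input-coefficient matrix and B the elementary-flow
intensity matrix.  Allocation follows the cut-off convention: recycled or
secondary inputs flagged as cut-off enter the system with zero upstream
burden (their technosphere column is empty).

Electricity use is regionalized by replacing a process's aggregate grid
input with technology-specific inputs weighted by an archetype's generation
mix, conserving total kWh exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .constants import COMPARTMENTS, TERMS
from .exceptions import MissingKeyError, NumericalError, SchemaError

__all__ = [
    "ProcessInventory",
    "TechnosphereSystem",
    "ElectricityMix",
    "build_system",
    "solve_inventory",
    "regionalize_electricity",
    "read_inventories_csv",
    "write_inventories_csv",
    "read_inventories_json",
    "write_inventories_json",
    "read_mixes_csv",
    "write_mixes_csv",
]

#: default identifier for the aggregate grid-electricity input that
#: regionalization replaces with per-technology inputs
GRID_PROCESS_ID = "electricity_grid"

# spectral-radius rejection threshold for the power-iteration solvability check
_RHO_MAX = 0.999
_RHO_ITERS = 200


@dataclass(frozen=True)
class ProcessInventory:
    """Unit-process dataset: exchanges per unit of declared output.

    Parameters
    ----------
    process_id : str
        Unique identifier of the process.
    unit : str
        Declared output unit (e.g. ``Mt``, ``kWh``, ``tkm``, ``wash-cycle``).
    technosphere_inputs : tuple of (process_id, amount)
        Inputs of other processes per unit output.
    elementary_emissions : tuple of (substance, compartment, term, amount)
        Direct environmental releases per unit output; ``compartment`` is one
        of air/water/soil/groundwater and ``term`` is ``short`` or ``long``.
    """

    process_id: str
    unit: str
    technosphere_inputs: tuple[tuple[str, float], ...] = ()
    elementary_emissions: tuple[tuple[str, str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for pid, amount in self.technosphere_inputs:
            if not np.isfinite(amount):
                raise SchemaError(
                    f"non-finite technosphere amount for input {pid!r} "
                    f"of process {self.process_id!r}"
                )
            if pid == self.process_id and amount >= 1:
                raise SchemaError(
                    f"process {self.process_id!r} consumes >= 1 unit of itself"
                )
        for sub, comp, term, amount in self.elementary_emissions:
            if comp not in COMPARTMENTS:
                raise SchemaError(
                    f"unknown compartment {comp!r} on emission {sub!r} "
                    f"of process {self.process_id!r}"
                )
            if term not in TERMS:
                raise SchemaError(
                    f"missing or unknown term {term!r} on emission {sub!r} "
                    f"of process {self.process_id!r} (expected one of {TERMS})"
                )
            if not np.isfinite(amount):
                raise SchemaError(
                    f"non-finite emission amount for {sub!r} "
                    f"of process {self.process_id!r}"
                )

    def scaled(self, factor: float) -> "ProcessInventory":
        """Return a copy with all exchange amounts multiplied by ``factor``."""
        return replace(
            self,
            technosphere_inputs=tuple(
                (p, a * factor) for p, a in self.technosphere_inputs
            ),
            elementary_emissions=tuple(
                (s, c, t, a * factor) for s, c, t, a in self.elementary_emissions
            ),
        )

    @property
    def is_empty(self) -> bool:
        """True for zero-effect processes (no inputs, no emissions)."""
        return not self.technosphere_inputs and not self.elementary_emissions


@dataclass(frozen=True)
class ElectricityMix:
    """Generation-technology shares of grid electricity for one archetype."""

    archetype_id: str
    shares: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise SchemaError(
                f"electricity-mix shares for {self.archetype_id!r} sum to "
                f"{total:.12g}, expected 1"
            )
        for tech, share in self.shares.items():
            if share < 0:
                raise SchemaError(
                    f"negative share {share} for technology {tech!r} "
                    f"in mix {self.archetype_id!r}"
                )


@dataclass(frozen=True)
class TechnosphereSystem:
    """Matrix form of a product system.

    ``A[i, j]`` is the amount of process ``i`` required per unit output of
    process ``j``; ``B[k, j]`` is the direct emission of elementary flow
    ``k`` (a substance/compartment/term triple) per unit of process ``j``.
    """

    A: np.ndarray
    B: np.ndarray
    process_index: tuple[str, ...]
    flow_index: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        n = len(self.process_index)
        if self.A.shape != (n, n):
            raise SchemaError(f"A has shape {self.A.shape}, expected ({n}, {n})")
        if self.B.shape != (len(self.flow_index), n):
            raise SchemaError(
                f"B has shape {self.B.shape}, expected "
                f"({len(self.flow_index)}, {n})"
            )

    def spectral_radius(self, iters: int = _RHO_ITERS, seed: int = 0) -> float:
        """Power-iteration estimate of the spectral radius of |A|."""
        n = self.A.shape[0]
        if n == 0 or not self.A.any():
            return 0.0
        rng = np.random.default_rng(seed)
        absA = np.abs(self.A)
        v = rng.random(n) + 1e-12
        rho = 0.0
        for _ in range(iters):
            w = absA @ v
            norm = np.linalg.norm(w)
            if norm == 0.0:
                return 0.0
            rho = norm / np.linalg.norm(v)
            v = w / norm
        return float(rho)

    def column(self, process_id: str) -> int:
        try:
            return self.process_index.index(process_id)
        except ValueError:
            raise MissingKeyError(
                f"process {process_id!r} not in system (has "
                f"{len(self.process_index)} processes)"
            ) from None


def build_system(
    inventories: list[ProcessInventory] | tuple[ProcessInventory, ...],
    cutoff_ids: frozenset[str] | set[str] = frozenset(),
) -> TechnosphereSystem:
    """Assemble the A and B matrices from unit-process inventories.

    ``cutoff_ids`` names secondary/recycled inputs that carry no upstream
    burden: they receive an empty technosphere column (cut-off allocation)
    so demanding them yields zero emissions.

    Raises
    ------
    SchemaError
        On duplicate process ids.
    MissingKeyError
        On a technosphere input referencing an undeclared process.
    """
    ids = [inv.process_id for inv in inventories]
    seen: set[str] = set()
    for pid in ids:
        if pid in seen:
            raise SchemaError(f"duplicate process id {pid!r}")
        seen.add(pid)

    all_ids = list(ids)
    for cid in sorted(cutoff_ids):
        if cid not in seen:
            all_ids.append(cid)
            seen.add(cid)

    dangling = sorted(
        {
            pid
            for inv in inventories
            for pid, _ in inv.technosphere_inputs
            if pid not in seen
        }
    )
    if dangling:
        raise MissingKeyError(
            "technosphere inputs reference undeclared processes: "
            + ", ".join(repr(d) for d in dangling)
        )

    col = {pid: j for j, pid in enumerate(all_ids)}
    flow_keys = sorted(
        {
            (s, c, t)
            for inv in inventories
            for s, c, t, _ in inv.elementary_emissions
        }
    )
    row = {key: i for i, key in enumerate(flow_keys)}

    n = len(all_ids)
    A = np.zeros((n, n))
    B = np.zeros((len(flow_keys), n))
    cutoff = set(cutoff_ids)
    for inv in inventories:
        if inv.process_id in cutoff:
            continue  # cut-off: column stays empty regardless of declared content
        j = col[inv.process_id]
        for pid, amount in inv.technosphere_inputs:
            A[col[pid], j] += amount
        for s, c, t, amount in inv.elementary_emissions:
            B[row[(s, c, t)], j] += amount

    return TechnosphereSystem(A=A, B=B, process_index=tuple(all_ids), flow_index=tuple(flow_keys))


def solve_inventory(
    system: TechnosphereSystem, demand: dict[str, float]
) -> pd.Series:
    """Total elementary emissions for a functional-unit demand.

    Computes ``g = B (I - A)^-1 f`` by dense LU factorization.  Returns a
    Series indexed by (substance, compartment, term).

    Raises
    ------
    NumericalError
        If the power-iteration spectral-radius estimate is >= 0.999
        (non-productive system) or the factorization is singular.
    SchemaError
        On empty or non-finite demand.
    """
    if not demand:
        raise SchemaError("demand vector is empty")
    f = np.zeros(len(system.process_index))
    for pid, amount in demand.items():
        if not np.isfinite(amount):
            raise SchemaError(f"non-finite demand for process {pid!r}")
        f[system.column(pid)] = amount

    rho = system.spectral_radius()
    if rho >= _RHO_MAX:
        raise NumericalError(
            f"technosphere system not solvable: spectral-radius estimate "
            f"{rho:.6f} >= {_RHO_MAX}"
        )
    ident = np.eye(len(system.process_index))
    try:
        lu, piv = scipy.linalg.lu_factor(ident - system.A)
        x = scipy.linalg.lu_solve((lu, piv), f)
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise NumericalError(
            f"LU solve failed (spectral-radius estimate {rho:.6f}): {exc}"
        ) from exc
    g = system.B @ x
    if not np.all(np.isfinite(g)):
        raise NumericalError("non-finite emissions in inventory solution")
    index = pd.MultiIndex.from_tuples(
        system.flow_index, names=["substance", "compartment", "term"]
    )
    return pd.Series(g, index=index, name="amount")


def regionalize_electricity(
    inventory: ProcessInventory,
    mix: ElectricityMix,
    technology_inventories: dict[str, ProcessInventory],
    grid_id: str = GRID_PROCESS_ID,
) -> ProcessInventory:
    """Replace an aggregate grid input with mix-weighted technology inputs.

    The inventory must carry exactly one technosphere input of ``grid_id``;
    it is split into per-technology inputs in proportion to the archetype's
    generation shares.  Total electricity demand (kWh) is conserved exactly.
    """
    grid_inputs = [
        (i, amt)
        for i, (pid, amt) in enumerate(inventory.technosphere_inputs)
        if pid == grid_id
    ]
    if len(grid_inputs) != 1:
        raise SchemaError(
            f"process {inventory.process_id!r} has {len(grid_inputs)} "
            f"{grid_id!r} inputs, expected exactly 1"
        )
    missing = sorted(set(mix.shares) - set(technology_inventories))
    if missing:
        raise MissingKeyError(
            "no inventory for electricity technologies: "
            + ", ".join(repr(m) for m in missing)
        )
    idx, kwh = grid_inputs[0]
    kept = [
        (pid, amt)
        for i, (pid, amt) in enumerate(inventory.technosphere_inputs)
        if i != idx
    ]
    # exact kWh conservation: assign share*kwh and put any rounding residue
    # on the largest-share technology
    techs = sorted(mix.shares, key=lambda t: (-mix.shares[t], t))
    amounts = {t: mix.shares[t] * kwh for t in techs}
    residue = kwh - sum(amounts.values())
    amounts[techs[0]] += residue
    per_tech = [
        (technology_inventories[t].process_id, amounts[t])
        for t in techs
        if amounts[t] != 0.0
    ]
    return replace(
        inventory, technosphere_inputs=tuple(kept) + tuple(per_tech)
    )


# ---------------------------------------------------------------------------
# External interfaces: CSV / JSON serialization
# ---------------------------------------------------------------------------

_INV_COLUMNS = [
    "process_id",
    "exchange_type",
    "target_id",
    "compartment",
    "term",
    "amount",
    "unit",
]


def write_inventories_csv(inventories: list[ProcessInventory], path) -> None:
    """One row per exchange, plus a declaring row for empty processes."""
    rows = []
    for inv in inventories:
        if inv.is_empty:
            rows.append((inv.process_id, "declaration", "", "", "", 0.0, inv.unit))
        for pid, amt in inv.technosphere_inputs:
            rows.append((inv.process_id, "technosphere", pid, "", "", amt, inv.unit))
        for s, c, t, amt in inv.elementary_emissions:
            rows.append((inv.process_id, "biosphere", s, c, t, amt, inv.unit))
    pd.DataFrame(rows, columns=_INV_COLUMNS).to_csv(path, index=False)


def read_inventories_csv(path) -> list[ProcessInventory]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_INV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"inventory CSV missing columns: {sorted(missing)}")
    out: list[ProcessInventory] = []
    for pid, grp in df.groupby("process_id", sort=False):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise SchemaError(f"process {pid!r} declares multiple units: {list(units)}")
        tech = []
        bio = []
        for rec in grp.itertuples(index=False):
            if rec.exchange_type == "technosphere":
                tech.append((rec.target_id, float(rec.amount)))
            elif rec.exchange_type == "biosphere":
                bio.append(
                    (rec.target_id, rec.compartment, rec.term, float(rec.amount))
                )
            elif rec.exchange_type != "declaration":
                raise SchemaError(
                    f"unknown exchange_type {rec.exchange_type!r} for {pid!r}"
                )
        out.append(
            ProcessInventory(
                process_id=str(pid),
                unit=str(units[0]),
                technosphere_inputs=tuple(tech),
                elementary_emissions=tuple(bio),
            )
        )
    return out


def write_inventories_json(inventories: list[ProcessInventory], path) -> None:
    payload = [
        {
            "process_id": inv.process_id,
            "unit": inv.unit,
            "technosphere_inputs": [list(x) for x in inv.technosphere_inputs],
            "elementary_emissions": [list(x) for x in inv.elementary_emissions],
        }
        for inv in inventories
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_inventories_json(path) -> list[ProcessInventory]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        ProcessInventory(
            process_id=rec["process_id"],
            unit=rec["unit"],
            technosphere_inputs=tuple(
                (str(p), float(a)) for p, a in rec["technosphere_inputs"]
            ),
            elementary_emissions=tuple(
                (str(s), str(c), str(t), float(a))
                for s, c, t, a in rec["elementary_emissions"]
            ),
        )
        for rec in payload
    ]


def write_mixes_csv(mixes: dict[str, ElectricityMix], path) -> None:
    rows = [
        (m.archetype_id, tech, share)
        for m in mixes.values()
        for tech, share in sorted(m.shares.items())
    ]
    pd.DataFrame(rows, columns=["archetype_id", "technology", "share"]).to_csv(
        path, index=False
    )


def read_mixes_csv(path) -> dict[str, ElectricityMix]:
    df = pd.read_csv(path)
    missing = {"archetype_id", "technology", "share"} - set(df.columns)
    if missing:
        raise SchemaError(f"mix CSV missing columns: {sorted(missing)}")
    return {
        str(aid): ElectricityMix(
            archetype_id=str(aid),
            shares={str(r.technology): float(r.share) for r in grp.itertuples()},
        )
        for aid, grp in df.groupby("archetype_id")
    }
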