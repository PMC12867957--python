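"""Shared fixtures: toy systems and a session-scoped synthetic world."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plasthealth import (
    CharacterizationTable,
    ElectricityMix,
    ProcessInventory,
    WorldConfig,
    gen_flows,
    gen_world,
)


@pytest.fixture(scope="session")
def world():
    """One synthetic world shared across the suite (fixed seed)."""
    return gen_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def world_flows(world):
    return gen_flows(world.config)


@pytest.fixture
def toy_table() -> CharacterizationTable:
    """Minimal factor table: two greenhouse gases, one particulate."""
    return CharacterizationTable(
        midpoint_factors={
            ("co2", "air", "global_warming"): 1.0,
            ("ch4", "air", "global_warming"): 29.8,
            ("pm25", "air", "fine_pm"): 1.0,
        },
        endpoint_factors={
            "global_warming": 9.28e-7,
            "fine_pm": 6.29e-4,
        },
    )


@pytest.fixture
def toy_inventories() -> list[ProcessInventory]:
    """Three-process chain: a -> b -> c with coefficients 0.5 and 0.2."""
    return [
        ProcessInventory(
            "proc_a", "Mt",
            technosphere_inputs=(("proc_b", 0.5),),
            elementary_emissions=(("co2", "air", "short", 10.0),),
        ),
        ProcessInventory(
            "proc_b", "kWh",
            technosphere_inputs=(("proc_c", 0.2),),
            elementary_emissions=(("ch4", "air", "short", 2.0),),
        ),
        ProcessInventory(
            "proc_c", "kg",
            elementary_emissions=(("pm25", "air", "short", 1.0),),
        ),
    ]


@pytest.fixture
def coal_wind_mixes() -> dict[str, ElectricityMix]:
    return {
        "coal_only": ElectricityMix("coal_only", {"elec_coal": 1.0}),
        "wind_only": ElectricityMix("wind_only", {"elec_wind": 1.0}),
    }


def random_flows(rng: np.random.Generator, n: int = 60) -> pd.DataFrame:
    """Random flow records over a tiny vocabulary (for oracle tests)."""
    return pd.DataFrame(
        {
            "year": rng.integers(2016, 2021, n),
            "scenario": rng.choice(["bau", "recycling"], n),
            "archetype": rng.choice(["hi_urban", "li_rural"], n),
            "material": rng.choice(["rigid_mono", "flexible_mono"], n),
            "stage": rng.choice(["production", "open_burning"], n),
            "mass_mt": rng.uniform(0.0, 5.0, n),
            "replicate": "point",
        }
    )
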