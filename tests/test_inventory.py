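"""Matrix inventory engine: assembly, solving, regionalization, IO."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasthealth import (
    ElectricityMix,
    MissingKeyError,
    NumericalError,
    ProcessInventory,
    SchemaError,
    build_system,
    regionalize_electricity,
    solve_inventory,
)
from plasthealth.inventory import (
    read_inventories_csv,
    read_inventories_json,
    read_mixes_csv,
    write_inventories_csv,
    write_inventories_json,
    write_mixes_csv,
)


def neumann_oracle(system, f: np.ndarray, k_max: int = 50) -> np.ndarray:
    """Brute-force truncated Neumann series: g = sum_k B A^k f."""
    x = np.zeros_like(f)
    term = f.copy()
    for _ in range(k_max + 1):
        x = x + term
        term = system.A @ term
    return system.B @ x


class TestBuildSystem:
    def test_independent_processes_have_zero_A(self):
        invs = [
            ProcessInventory("p", "Mt", elementary_emissions=(("co2", "air", "short", 1.0),)),
            ProcessInventory("q", "Mt", elementary_emissions=(("ch4", "air", "short", 2.0),)),
        ]
        system = build_system(invs)
        assert not system.A.any()
        # each process's emissions sit in its own column
        gp = solve_inventory(system, {"p": 1.0})
        assert gp[("co2", "air", "short")] == 1.0
        assert gp[("ch4", "air", "short")] == 0.0

    def test_direct_coefficient_read_off(self, toy_inventories):
        system = build_system(toy_inventories)
        i = system.process_index.index
        assert system.A[i("proc_b"), i("proc_a")] == 0.5
        assert system.A[i("proc_c"), i("proc_b")] == 0.2

    def test_dangling_reference_names_missing_id(self):
        inv = ProcessInventory(
            "p", "Mt", technosphere_inputs=(("grid_mix_X", 1.0),)
        )
        with pytest.raises(MissingKeyError, match="grid_mix_X"):
            build_system([inv])

    def test_duplicate_id_rejected(self):
        inv = ProcessInventory("p", "Mt")
        with pytest.raises(SchemaError, match="duplicate"):
            build_system([inv, inv])

    def test_cutoff_input_contributes_nothing(self, toy_inventories):
        # vary the amount of a cut-off (recycled) input: g must not change
        def with_cutoff(amount):
            inv = ProcessInventory(
                "proc_a", "Mt",
                technosphere_inputs=(("recyclate", amount),),
                elementary_emissions=(("co2", "air", "short", 10.0),),
            )
            system = build_system([inv], cutoff_ids={"recyclate"})
            return solve_inventory(system, {"proc_a": 1.0})

        g1, g2 = with_cutoff(0.1), with_cutoff(0.9)
        assert (g1 == g2).all()
        assert g1[("co2", "air", "short")] == 10.0


class TestSolveInventory:
    def test_three_process_toy_matches_neumann_series(self, toy_inventories):
        system = build_system(toy_inventories)
        f = np.zeros(3)
        f[system.process_index.index("proc_a")] = 1.0
        g = solve_inventory(system, {"proc_a": 1.0})
        expected = neumann_oracle(system, f)
        np.testing.assert_allclose(g.to_numpy(), expected, atol=1e-9)

    def test_zero_demand_gives_zero(self, toy_inventories):
        system = build_system(toy_inventories)
        g = solve_inventory(system, {"proc_a": 0.0})
        assert (g == 0).all()

    def test_empty_demand_rejected(self, toy_inventories):
        with pytest.raises(SchemaError):
            solve_inventory(build_system(toy_inventories), {})

    def test_non_productive_system_reports_spectral_radius(self):
        invs = [
            ProcessInventory("p", "Mt", technosphere_inputs=(("q", 1.2),)),
            ProcessInventory("q", "Mt", technosphere_inputs=(("p", 1.1),),
                             elementary_emissions=(("co2", "air", "short", 1.0),)),
        ]
        with pytest.raises(NumericalError, match="spectral-radius"):
            solve_inventory(build_system(invs), {"p": 1.0})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_random_small_systems_match_oracle(self, seed):
        """Direct LU solve equals the Neumann-series oracle to 1e-8."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        A = rng.random((n, n)) * rng.random((n, n))
        A *= 0.85 / max(np.abs(np.linalg.eigvals(A)).max(), 1e-12)
        B = rng.random((3, n))
        invs = []
        for j in range(n):
            tech = tuple(
                (f"p{i}", float(A[i, j])) for i in range(n) if A[i, j] > 0
            )
            bio = tuple(
                (f"s{k}", "air", "short", float(B[k, j])) for k in range(3)
            )
            invs.append(ProcessInventory(f"p{j}", "Mt", tech, bio))
        system = build_system(invs)
        f = np.zeros(n)
        j0 = system.process_index.index("p0")
        f[j0] = float(rng.uniform(0.5, 2.0))
        g = solve_inventory(system, {"p0": float(f[j0])})
        expected = neumann_oracle(system, f, k_max=400)
        np.testing.assert_allclose(
            g.to_numpy(), expected, rtol=1e-8, atol=1e-10
        )

    def test_linearity(self, toy_inventories):
        system = build_system(toy_inventories)
        g1 = solve_inventory(system, {"proc_a": 1.0})
        g2 = solve_inventory(system, {"proc_b": 1.0})
        combo = solve_inventory(system, {"proc_a": 2.5, "proc_b": -0.5})
        np.testing.assert_allclose(
            combo.to_numpy(), (2.5 * g1 - 0.5 * g2).to_numpy(), rtol=1e-9
        )


COAL = ProcessInventory(
    "elec_coal", "kWh", elementary_emissions=(("co2", "air", "short", 1.0),)
)
WIND = ProcessInventory(
    "elec_wind", "kWh", elementary_emissions=(("co2", "air", "short", 0.01),)
)
TECHS = {"elec_coal": COAL, "elec_wind": WIND}
FACTORY = ProcessInventory(
    "factory", "Mt",
    technosphere_inputs=(("electricity_grid", 100.0),),
    elementary_emissions=(("co2", "air", "short", 5.0),),
)


class TestRegionalization:
    def _solve_co2(self, inv):
        system = build_system([inv, COAL, WIND])
        return float(solve_inventory(system, {"factory": 1.0})[("co2", "air", "short")])

    def test_identity_mix_preserves_emissions(self):
        # reference grid implemented as an explicit mix process
        grid = ProcessInventory(
            "electricity_grid", "kWh",
            technosphere_inputs=(("elec_coal", 0.6), ("elec_wind", 0.4)),
        )
        system = build_system([FACTORY, grid, COAL, WIND])
        original = solve_inventory(system, {"factory": 1.0})
        mix = ElectricityMix("ref", {"elec_coal": 0.6, "elec_wind": 0.4})
        reg = regionalize_electricity(FACTORY, mix, TECHS)
        regionalized = solve_inventory(
            build_system([reg, COAL, WIND]), {"factory": 1.0}
        )
        np.testing.assert_allclose(
            regionalized.to_numpy(), original.to_numpy(), atol=1e-12
        )

    def test_coal_vs_wind_difference_hand_computed(self):
        coal_mix = ElectricityMix("c", {"elec_coal": 1.0})
        wind_mix = ElectricityMix("w", {"elec_wind": 1.0})
        co2_coal = self._solve_co2(regionalize_electricity(FACTORY, coal_mix, TECHS))
        co2_wind = self._solve_co2(regionalize_electricity(FACTORY, wind_mix, TECHS))
        # (coal - wind per-kWh emissions) x kWh demand = (1.0 - 0.01) x 100
        assert co2_coal - co2_wind == pytest.approx(99.0, abs=1e-9)

    def test_fossil_share_monotone_in_co2(self):
        values = []
        for share in np.linspace(0.0, 1.0, 11):
            mix = ElectricityMix(
                "m", {"elec_coal": float(share), "elec_wind": float(1 - share)}
            )
            values.append(
                self._solve_co2(regionalize_electricity(FACTORY, mix, TECHS))
            )
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_kwh_conserved_exactly(self):
        mix = ElectricityMix("m", {"elec_coal": 1 / 3, "elec_wind": 2 / 3})
        reg = regionalize_electricity(FACTORY, mix, TECHS)
        total = sum(
            a for p, a in reg.technosphere_inputs if p.startswith("elec_")
        )
        assert total == 100.0

    def test_bad_shares_rejected(self):
        with pytest.raises(SchemaError, match="sum to"):
            ElectricityMix("m", {"elec_coal": 0.5, "elec_wind": 0.4})

    def test_missing_technology_inventory(self):
        mix = ElectricityMix("m", {"elec_coal": 0.5, "elec_nuclear": 0.5})
        with pytest.raises(MissingKeyError, match="elec_nuclear"):
            regionalize_electricity(FACTORY, mix, TECHS)


class TestInventoryValidation:
    def test_self_input_at_unity_rejected(self):
        with pytest.raises(SchemaError, match="itself"):
            ProcessInventory("p", "Mt", technosphere_inputs=(("p", 1.0),))

    def test_missing_term_rejected(self):
        with pytest.raises(SchemaError, match="term"):
            ProcessInventory(
                "p", "Mt", elementary_emissions=(("co2", "air", "", 1.0),)
            )


class TestRoundTrips:
    def test_csv_round_trip(self, toy_inventories, tmp_path):
        path = tmp_path / "inv.csv"
        write_inventories_csv(toy_inventories, path)
        back = read_inventories_csv(path)
        assert back == toy_inventories

    def test_json_round_trip(self, toy_inventories, tmp_path):
        path = tmp_path / "inv.json"
        write_inventories_json(toy_inventories, path)
        assert read_inventories_json(path) == toy_inventories

    def test_mix_round_trip(self, tmp_path):
        mixes = {"a1": ElectricityMix("a1", {"elec_coal": 0.25, "elec_wind": 0.75})}
        path = tmp_path / "mix.csv"
        write_mixes_csv(mixes, path)
        assert read_mixes_csv(path) == mixes

    def test_empty_process_survives_round_trip(self, tmp_path):
        invs = [ProcessInventory("zero_effect", "Mt")]
        path = tmp_path / "inv.csv"
        write_inventories_csv(invs, path)
        assert read_inventories_csv(path) == invs
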