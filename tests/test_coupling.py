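"""Flow-factor coupling, credits, substitution, aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plasthealth import (
    CreditRule,
    FactorTable,
    MissingKeyError,
    SchemaError,
    SubstitutionSpec,
    aggregate,
    apply_credits,
    apply_substitution,
    contribution_analysis,
    couple,
    percent_reduction,
)
from plasthealth.blocks import UnitImpactFactor
from plasthealth.characterization import MidpointVector
from plasthealth.constants import MIDPOINTS
from plasthealth.coupling import SAME_MATERIAL, read_flows_csv, write_flows_csv

from conftest import random_flows


def make_factor(material, stage, archetype, dalys, midpoint="global_warming"):
    mv = MidpointVector(
        values={midpoint: dalys}, daly_values={midpoint: dalys}
    )
    return UnitImpactFactor(
        material_id=material, stage_id=stage, archetype_id=archetype,
        dalys_per_unit=dalys, midpoint_breakdown=mv,
    )


@pytest.fixture
def toy_factors() -> FactorTable:
    factors = []
    for material, stage, dalys in [
        ("rigid_mono", "production", 10.0),
        ("rigid_mono", "open_burning", 5.0),
        ("rigid_mono", "mechanical_recycling_open", 1.0),
        ("flexible_mono", "production", 8.0),
        ("flexible_mono", "open_burning", 4.0),
        ("lower_grade_polymer", "production", 100.0),
        ("paper", "lifecycle", 2.0),
    ]:
        for archetype in ["hi_urban", "li_rural"]:
            factors.append(make_factor(material, stage, archetype, dalys))
    return FactorTable.from_factors(factors)


def flow(year, scenario, archetype, material, stage, mass):
    return dict(
        year=year, scenario=scenario, archetype=archetype, material=material,
        stage=stage, mass_mt=mass, replicate="point",
    )


class TestCouple:
    def test_zero_masses_zero_ledger(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 0.0),
            flow(2016, "bau", "hi_urban", "rigid_mono", "open_burning", 0.0),
        ])
        ledger = couple(flows, toy_factors)
        assert (ledger["dalys"] == 0).all()

    def test_hand_product_sum(self, toy_factors):
        # 3 Mt x 10 DALY/Mt + 1 Mt x 5 DALY/Mt = 35 DALYs
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 3.0),
            flow(2016, "bau", "hi_urban", "rigid_mono", "open_burning", 1.0),
        ])
        assert couple(flows, toy_factors)["dalys"].sum() == pytest.approx(35.0)

    def test_missing_factor_is_hard_error(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "chemical_recycling", 1.0)
        ])
        with pytest.raises(MissingKeyError, match="chemical_recycling"):
            couple(flows, toy_factors)

    def test_negative_mass_rejected(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", -1.0)
        ])
        with pytest.raises(SchemaError, match="negative mass"):
            couple(flows, toy_factors)

    def test_order_independence(self, toy_factors):
        rng = np.random.default_rng(11)
        flows = random_flows(rng)
        a = aggregate(couple(flows, toy_factors))
        shuffled = flows.sample(frac=1.0, random_state=5).reset_index(drop=True)
        b = aggregate(couple(shuffled, toy_factors))
        pd.testing.assert_frame_equal(a.totals, b.totals)

    def test_midpoint_scaling_matches_total(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 2.5)
        ])
        ledger = couple(flows, toy_factors)
        assert ledger["daly_global_warming"].iloc[0] == pytest.approx(25.0)
        assert ledger["dalys"].iloc[0] == pytest.approx(25.0)


class TestCredits:
    def test_no_trigger_flows_no_change(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 2.0)
        ])
        ledger = couple(flows, toy_factors)
        out = apply_credits(
            ledger, flows,
            [CreditRule("mechanical_recycling_open", "lower_grade_polymer", 0.8)],
            toy_factors,
        )
        pd.testing.assert_frame_equal(out, ledger)

    def test_hand_credit(self, toy_factors):
        # 1 Mt recyclate, yield 0.8, avoided factor 100 -> credit -80 DALYs
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono",
                 "mechanical_recycling_open", 1.0)
        ])
        ledger = couple(flows, toy_factors)
        out = apply_credits(
            ledger, flows,
            [CreditRule("mechanical_recycling_open", "lower_grade_polymer", 0.8)],
            toy_factors,
        )
        credit = out.loc[out["direction"] == "avoided"]
        assert len(credit) == 1
        assert credit["dalys"].iloc[0] == pytest.approx(-80.0)
        assert credit["source_stage"].iloc[0] == "mechanical_recycling_open"

    def test_same_material_sentinel(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono",
                 "mechanical_recycling_open", 2.0)
        ])
        out = apply_credits(
            couple(flows, toy_factors), flows,
            [CreditRule("mechanical_recycling_open", SAME_MATERIAL, 0.5)],
            toy_factors,
        )
        credit = out.loc[out["direction"] == "avoided"]
        assert credit["material"].iloc[0] == "rigid_mono"
        # 2 Mt x 0.5 x 10 DALY/Mt production factor
        assert credit["dalys"].iloc[0] == pytest.approx(-10.0)

    def test_unknown_stage_rejected(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 1.0)
        ])
        with pytest.raises(SchemaError, match="unknown stage"):
            apply_credits(
                couple(flows, toy_factors), flows,
                [CreditRule("imaginary_stage", "lower_grade_polymer", 0.5)],
                toy_factors,
            )

    def test_credit_bounded_by_avoided_factor(self, toy_factors):
        rng = np.random.default_rng(4)
        masses = rng.uniform(0, 10, 20)
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono",
                 "mechanical_recycling_open", float(m))
            for m in masses
        ])
        out = apply_credits(
            couple(flows, toy_factors), flows,
            [CreditRule("mechanical_recycling_open", "lower_grade_polymer", 1.0)],
            toy_factors,
        )
        credits = out.loc[out["direction"] == "avoided", "dalys"].to_numpy()
        bound = 100.0 * masses  # avoided-production factor x mass
        assert (np.abs(credits) <= bound + 1e-9).all()

    def test_yield_outside_unit_interval_rejected(self):
        with pytest.raises(SchemaError, match="yield"):
            CreditRule("s", "m", 1.2)


class TestSubstitution:
    def displaced(self, mass, substitute="paper"):
        return pd.DataFrame([
            dict(year=2016, scenario="reduce_substitute", archetype="hi_urban",
                 substitute=substitute, displaced_mass_mt=mass, replicate="point")
        ])

    def test_one_to_one_ratio(self, toy_factors):
        specs = {"paper": SubstitutionSpec("paper", 1.0, stage_id="lifecycle")}
        sub_flows, ledger = apply_substitution(self.displaced(10.0), specs, toy_factors)
        assert sub_flows["mass_mt"].iloc[0] == pytest.approx(10.0)
        assert ledger["dalys"].iloc[0] == pytest.approx(20.0)

    @pytest.mark.parametrize("ratio,expected", [(0.4, 4.0), (9.0, 90.0)])
    def test_ratio_range_endpoints(self, toy_factors, ratio, expected):
        specs = {
            "paper": SubstitutionSpec("paper", ratio, (0.4, 9.0), stage_id="lifecycle")
        }
        sub_flows, _ = apply_substitution(self.displaced(10.0), specs, toy_factors)
        assert sub_flows["mass_mt"].iloc[0] == pytest.approx(expected)

    def test_zero_displaced_no_records(self, toy_factors):
        specs = {"paper": SubstitutionSpec("paper", 1.0, stage_id="lifecycle")}
        sub_flows, ledger = apply_substitution(self.displaced(0.0), specs, toy_factors)
        assert sub_flows.empty and ledger.empty

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(SchemaError, match="positive"):
            SubstitutionSpec("paper", 0.0)

    def test_missing_spec_rejected(self, toy_factors):
        with pytest.raises(MissingKeyError, match="bamboo"):
            apply_substitution(self.displaced(1.0, "bamboo"), {}, toy_factors)


class TestAggregate:
    def test_single_record(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 2.0)
        ])
        result = aggregate(couple(flows, toy_factors))
        assert result.total("bau", 2016) == pytest.approx(20.0)
        assert result.cumulative["bau"] == pytest.approx(20.0)

    def test_groupby_oracle_every_dimension(self, toy_factors):
        rng = np.random.default_rng(2)
        flows = random_flows(rng, n=120)
        ledger = couple(flows, toy_factors)
        result = aggregate(ledger)
        for dim in ["stage", "archetype", "material", "direction"]:
            expected = {}
            for rec in ledger.itertuples(index=False):
                key = getattr(rec, dim)
                expected[key] = expected.get(key, 0.0) + rec.dalys
            got = result.breakdown(dim)
            assert set(got.index) == set(expected)
            for key, val in expected.items():
                assert got[key] == pytest.approx(val, rel=1e-9)

    def test_closure_all_dimensions(self, toy_factors):
        rng = np.random.default_rng(8)
        flows = random_flows(rng, n=200)
        ledger = couple(flows, toy_factors)
        result = aggregate(ledger)
        net = float(ledger["dalys"].sum())
        for dim in ["midpoint", "stage", "archetype", "material", "direction"]:
            assert result.breakdown(dim).sum() == pytest.approx(net, rel=1e-9)

    def test_induced_and_avoided_split(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono",
                 "mechanical_recycling_open", 1.0)
        ])
        ledger = apply_credits(
            couple(flows, toy_factors), flows,
            [CreditRule("mechanical_recycling_open", "lower_grade_polymer", 0.5)],
            toy_factors,
        )
        result = aggregate(ledger)
        assert result.induced_total("bau", 2016) == pytest.approx(1.0)
        assert result.total("bau", 2016) == pytest.approx(1.0 - 50.0)


class TestPercentReduction:
    def _result(self, ref_total, target_total, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", ref_total / 10.0),
            flow(2016, "recycling", "hi_urban", "rigid_mono", "production",
                 target_total / 10.0),
        ])
        return aggregate(couple(flows, toy_factors))

    def test_identical_scenarios_zero(self, toy_factors):
        result = self._result(200.0, 200.0, toy_factors)
        red = percent_reduction(result, "bau", "recycling", window=(2016, 2016))
        assert red["percent"] == pytest.approx(0.0)

    def test_toy_hand_arithmetic(self, toy_factors):
        result = self._result(200.0, 150.0, toy_factors)
        red = percent_reduction(result, "bau", "recycling", window=(2016, 2016))
        assert red["percent"] == pytest.approx(25.0)

    def test_unrounded_vs_printed_convention(self, toy_factors):
        # cumulative totals of 83 vs 65 (million) give 21.7% unrounded
        result = self._result(83e6, 65e6, toy_factors)
        red = percent_reduction(result, "bau", "recycling", window=(2016, 2016))
        assert red["percent"] == pytest.approx(100 * 18 / 83, rel=1e-9)
        assert 21.0 <= red["percent"] <= 22.0

    def test_zero_reference_rejected(self, toy_factors):
        result = self._result(0.0, 0.0, toy_factors)
        with pytest.raises(SchemaError, match="reference"):
            percent_reduction(result, "bau", "recycling", window=(2016, 2016))

    def test_missing_scenario_rejected(self, toy_factors):
        result = self._result(1.0, 1.0, toy_factors)
        with pytest.raises(MissingKeyError):
            percent_reduction(result, "bau", "system_change", window=(2016, 2016))


class TestContributions:
    def test_single_stage_hundred_percent(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 1.0)
        ])
        shares = contribution_analysis(
            aggregate(couple(flows, toy_factors)), "stage"
        )
        assert shares["share_pct"].iloc[0] == pytest.approx(100.0)

    def test_shares_match_bruteforce_and_sum_to_100(self, toy_factors):
        rng = np.random.default_rng(13)
        flows = random_flows(rng, n=150)
        result = aggregate(couple(flows, toy_factors))
        shares = contribution_analysis(result, "archetype")
        bd = result.breakdown("archetype")
        total = bd.sum()
        for key, val in bd.items():
            assert shares.loc[key, "share_pct"] == pytest.approx(100 * val / total)
        assert shares["share_pct"].sum() == pytest.approx(100.0)

    def test_threshold_pools_into_other(self, toy_factors):
        rng = np.random.default_rng(14)
        flows = random_flows(rng, n=150)
        result = aggregate(couple(flows, toy_factors))
        shares = contribution_analysis(result, "stage", threshold=45.0)
        assert "other" in shares.index or len(shares) == len(result.breakdown("stage"))
        assert shares["share_pct"].sum() == pytest.approx(100.0)

    def test_unknown_dimension_rejected(self, toy_factors):
        flows = pd.DataFrame([
            flow(2016, "bau", "hi_urban", "rigid_mono", "production", 1.0)
        ])
        with pytest.raises(SchemaError, match="dimension"):
            contribution_analysis(
                aggregate(couple(flows, toy_factors)), "flavour"
            )


def test_flows_csv_round_trip(tmp_path):
    rng = np.random.default_rng(21)
    flows = random_flows(rng, n=30)
    path = tmp_path / "flows.csv"
    write_flows_csv(flows, path)
    back = read_flows_csv(path)
    pd.testing.assert_frame_equal(
        back, flows, check_dtype=False
    )


def test_flows_csv_column_mapping(tmp_path):
    rng = np.random.default_rng(22)
    flows = random_flows(rng, n=10).rename(
        columns={"mass_mt": "Mass_Mt_yr", "material": "plastic_category"}
    )
    path = tmp_path / "flows.csv"
    flows.to_csv(path, index=False)
    back = read_flows_csv(
        path, column_map={"Mass_Mt_yr": "mass_mt", "plastic_category": "material"}
    )
    assert back["mass_mt"].sum() == pytest.approx(flows["Mass_Mt_yr"].sum())
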