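"""Cost standardization: currency conversion, allocation, summaries, composition."""

from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgcea import (
    AllocationRule,
    CostLedger,
    CostLineItem,
    CurrencySpec,
    allocate_joint_costs,
    apply_factorial_allocation,
    composition_shares,
    convert_currency,
    load_fixture,
    summarize_costs,
)
from wgcea._util import round_half_away

from conftest import reconstructed_ledger


def item(amount, category="staff", phase="implementation", joint=False, period=0):
    return CostLineItem(period=period, amount=Decimal(str(amount)), category=category,
                        phase=phase, joint=joint)


class TestConvertCurrency:
    @pytest.mark.parametrize(
        "amount,ratio,ppp,expected",
        [(100, 1.0, 1.0, 100.0), (1000, 1.20, 24.0, 50.0), (0, 1.5, 7.0, 0.0)],
    )
    def test_inflate_then_ppp(self, amount, ratio, ppp, expected):
        spec = CurrencySpec("LCU", 2010, {2010: 1.0, 2016: ratio}, ppp)
        assert convert_currency(amount, spec) == pytest.approx(expected)

    def test_missing_deflator_year_is_an_error(self):
        spec = CurrencySpec("LCU", 2005, {2010: 1.0, 2016: 1.2}, 10.0)
        with pytest.raises(KeyError):
            convert_currency(100, spec)


class TestJointAllocation:
    def test_joint_items_scaled_others_untouched(self):
        ledger = CostLedger.from_items([item(100, joint=True), item(50, joint=False)])
        out = allocate_joint_costs(ledger, AllocationRule(joint_share=0.30))
        assert [float(i.amount) for i in out] == [30.0, 50.0]
        assert len(out) == len(ledger)

    def test_base_case_share_example(self):
        # a 40% rule attributes 40 of a shared 100 to the intervention
        out = allocate_joint_costs(
            CostLedger.from_items([item(100, joint=True)]), AllocationRule(joint_share=0.40)
        )
        assert float(out.total()) == pytest.approx(40.0)

    def test_share_one_is_identity(self):
        ledger = CostLedger.from_items([item(100, joint=True), item(7, joint=False)])
        out = allocate_joint_costs(ledger, AllocationRule(joint_share=1.0))
        assert out == ledger

    def test_per_category_share_missing_category_errors(self):
        ledger = CostLedger.from_items([item(10, category="capital", joint=True)])
        with pytest.raises(KeyError):
            allocate_joint_costs(ledger, AllocationRule(joint_share={"staff": 0.4}))

    @given(share=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_share(self, share):
        ledger = CostLedger.from_items([item(100, joint=True), item(50)])
        lo = allocate_joint_costs(ledger, AllocationRule(joint_share=share)).total()
        hi = allocate_joint_costs(ledger, AllocationRule(joint_share=min(1.0, share + 0.1))).total()
        assert lo <= hi


class TestSummarize:
    def test_nepal_annual_and_unit_costs(self, trials):
        profile, reported = trials["Nepal"]
        summary = summarize_costs(reconstructed_ledger(reported), profile)
        assert round_half_away(summary.annual_total_cost) == 389005
        assert round_half_away(summary.cost_per_live_birth) == 537
        assert round_half_away(summary.annual_cost_per_group) == 3505
        assert round_half_away(summary.annual_cost_per_person, 1) == 4.5

    def test_annualization_is_12_over_horizon_months(self, trials):
        profile, reported = trials["India"]
        summary = summarize_costs(reconstructed_ledger(reported), profile)
        assert summary.annual_total_cost == pytest.approx(797212 * 12 / 49)
        assert summary.annual_implementation_cost == pytest.approx((797212 - 308810) * 12 / 49)

    def test_empty_ledger_all_zero_composition_undefined(self, trials):
        profile, _ = trials["Nepal"]
        summary = summarize_costs(CostLedger.from_items([]), profile)
        assert summary.total_cost == summary.startup_cost == summary.cost_per_live_birth == 0
        assert summary.composition is None

    @given(k=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity_in_ledger_scale(self, k, trials):
        profile, _ = trials["BangladeshII"]
        base_items = [item(1000, "staff", "startup"), item(2500, "other_recurrent"),
                      item(400, "capital"), item(80, "materials")]
        kd = Decimal(str(k))
        base = summarize_costs(CostLedger.from_items(base_items), profile)
        scaled = summarize_costs(
            CostLedger.from_items([item(float(i.amount * kd), i.category, i.phase) for i in base_items]),
            profile,
        )
        for f in ("total_cost", "startup_cost", "annual_total_cost", "cost_per_live_birth"):
            assert getattr(scaled, f) == pytest.approx(k * getattr(base, f), rel=1e-9)
        for cat, share in base.composition.items():
            assert scaled.composition[cat] == pytest.approx(share, abs=1e-9)

    @given(
        amounts=st.lists(st.decimals(min_value=0, max_value=10**7, places=2), min_size=1, max_size=20),
        phases=st.data(),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_startup_plus_implementation_partitions_total(self, amounts, phases, trials):
        profile, _ = trials["India"]
        items = [
            item(a, phase=phases.draw(st.sampled_from(["startup", "implementation"])))
            for a in amounts
        ]
        s = summarize_costs(CostLedger.from_items(items), profile)
        assert s.startup_cost + s.implementation_cost == pytest.approx(s.total_cost, abs=1e-9)
        assert s.total_cost == pytest.approx(float(sum(Decimal(str(a)) for a in amounts)))


class TestComposition:
    def test_single_category(self):
        assert composition_shares(CostLedger.from_items([item(10)])) == {
            "staff": 1.0, "materials": 0.0, "other_recurrent": 0.0, "capital": 0.0
        }

    def test_four_category_split(self):
        ledger = CostLedger.from_items(
            [item(65, "staff"), item(2, "materials"), item(18, "other_recurrent"), item(15, "capital")]
        )
        shares = composition_shares(ledger)
        assert shares == pytest.approx(
            {"staff": 0.65, "materials": 0.02, "other_recurrent": 0.18, "capital": 0.15}
        )
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            composition_shares(CostLedger.from_items([]))


class TestFactorialAllocation:
    def test_maikhanda_bounds_reproduce_published_cers(self, trials):
        from wgcea import CostSummary

        profile, reported = trials["MaiKhanda"]
        base = CostSummary.from_reported(profile, reported)
        low = apply_factorial_allocation(base, 0.33)
        high = apply_factorial_allocation(base, 0.75)
        assert low.total_cost == pytest.approx(444687 + (3064842 - 444687) * 0.33 / 0.5)
        assert round_half_away(low.total_cost / reported.neonatal_lys) == 202
        assert round_half_away(high.total_cost / reported.neonatal_lys) == 406

    def test_half_share_is_identity(self, trials):
        from wgcea import CostSummary

        profile, reported = trials["MaiMwana"]
        base = CostSummary.from_reported(profile, reported)
        assert apply_factorial_allocation(base, 0.5) == base

    def test_inverse_reallocation_recovers_base(self, trials):
        from wgcea import CostSummary

        profile, reported = trials["MaiKhanda"]
        base = CostSummary.from_reported(profile, reported)
        forth = apply_factorial_allocation(base, 0.33)
        back = apply_factorial_allocation(forth, 0.5 * 0.5 / 0.33)
        assert back.total_cost == pytest.approx(base.total_cost, rel=1e-12)
        assert back.implementation_cost == pytest.approx(base.implementation_cost, rel=1e-12)

    def test_share_outside_unit_interval_errors(self, trials):
        from wgcea import CostSummary

        profile, reported = trials["MaiKhanda"]
        base = CostSummary.from_reported(profile, reported)
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                apply_factorial_allocation(base, bad)


def test_ledger_csv_round_trip(tmp_path):
    ledger = CostLedger.from_items(
        [item(123.45, "capital", "startup", joint=True, period=3), item(9.99, period=20)]
    )
    path = tmp_path / "ledger.csv"
    ledger.to_csv(path)
    assert CostLedger.read_csv(path) == ledger
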