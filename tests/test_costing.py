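"""Unit tests for the micro-costing engine against hand-computed oracles."""

import math

import pytest

import oacost as oc
from oacost.costing import Category, Domain, Mode, Role


def make_ctx(**overrides) -> oc.ValuationContext:
    base = dict(provider_gross_hourly_wage=200.0,
                population_gross_hourly_wage=196.6)
    base.update(overrides)
    return oc.ValuationContext(**base)


class TestValueLabourTime:
    @pytest.mark.parametrize("hours, wage, role, on_site, expected", [
        # 1 h x 200 x 1.3142, off site
        (1.0, 200.0, Role.PROVIDER, False, 262.84),
        # hand oracle: 2 x 196.6 x 0.3
        (2.0, 196.6, Role.PATIENT_LEISURE, False, 117.96),
        # full gross wage, no social fees
        (2.0, 196.6, Role.PATIENT_FULL, False, 393.2),
        # facility surcharge multiplies the provider rate: 262.84 x 1.1
        (1.0, 200.0, Role.PROVIDER, True, 289.124),
        (0.0, 500.0, Role.PROVIDER, True, 0.0),
    ])
    def test_valuation_rules(self, hours, wage, role, on_site, expected):
        ctx = make_ctx()
        value = oc.value_labour_time(hours, wage, role, ctx, on_site=on_site)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_negative_inputs_rejected(self):
        ctx = make_ctx()
        with pytest.raises(oc.ValidationError):
            oc.value_labour_time(-1.0, 200.0, Role.PROVIDER, ctx)
        with pytest.raises(oc.ValidationError):
            oc.value_labour_time(1.0, -200.0, Role.PROVIDER, ctx)


class TestGroupAllocation:
    def test_identity_at_group_size_one(self):
        assert oc.allocate_group_session(8778.0, 1) == 8778.0

    def test_division(self):
        assert oc.allocate_group_session(8778.0, 14) == pytest.approx(627.0)

    def test_degenerate_group_rejected(self):
        with pytest.raises(oc.ValidationError):
            oc.allocate_group_session(100.0, 0)


class TestSupportAndTraining:
    def test_support_unit_cost(self):
        assert oc.technical_support_unit_cost(100_000, 1_000) == 100.0
        assert oc.technical_support_unit_cost(100_000, 1_000, halved=True) == 50.0
        assert oc.technical_support_unit_cost(0, 1_000) == 0.0
        with pytest.raises(oc.ValidationError):
            oc.technical_support_unit_cost(100_000, 0)

    def test_training_amortization_oracle(self):
        # 2 x 200 x 1.5 / 60 with zero social fees
        ctx = make_ctx(social_fee_rate=0.0)
        assert oc.amortize_training(2.0, 200.0, ctx, 60) == pytest.approx(10.0)
        assert oc.amortize_training(0.0, 200.0, ctx, 60) == 0.0
        with pytest.raises(oc.ValidationError):
            oc.amortize_training(2.0, 200.0, ctx, 0)

    def test_published_training_lines_from_fixtures(self, ctx, boa, ja):
        """The calibrated parameters admit the published 30 / 11 SEK lines."""
        for spec, expected in ((boa, 30), (ja, 11)):
            value = oc.amortize_training(
                spec.training_hours_per_provider, ctx.provider_gross_hourly_wage,
                ctx, spec.episodes_per_provider)
            assert oc.round_sek(value) == expected


class TestScheduleBuilding:
    def test_digital_protocol_expands_to_18_contacts_143_minutes(self, ja):
        count, provider_min, patient_min = oc.build_episode_schedule(ja)
        assert count == 18
        assert provider_min == pytest.approx(142.5)
        assert oc.round_sek(provider_min) == 143
        assert patient_min == pytest.approx(142.5)

    def test_empty_schedule(self):
        spec = oc.CareModelSpec(name="empty")
        assert oc.build_episode_schedule(spec) == (0, 0.0, 0.0)

    def test_face_to_face_protocol_has_28_contact_hours(self, boa):
        count, provider_min, patient_min = oc.build_episode_schedule(boa)
        assert count == 28
        assert provider_min == pytest.approx(28 * 60)
        assert patient_min == pytest.approx(28 * 60)

    @pytest.mark.parametrize("policy, expected", [
        (oc.MidpointPolicy.MIDPOINT, 6.5),
        (oc.MidpointPolicy.LOW, 5.0),
        (oc.MidpointPolicy.HIGH, 8.0),
    ])
    def test_range_resolution_policies(self, policy, expected):
        contact = oc.ContactEvent(label="weekly", mode=Mode.PLATFORM,
                                  duration_low=5, duration_high=8)
        assert contact.resolved_minutes(policy) == expected

    def test_invalid_contacts_rejected(self):
        with pytest.raises(oc.ValidationError):
            oc.ContactEvent(label="bad", mode=Mode.PLATFORM,
                            duration_minutes=-1)
        with pytest.raises(oc.ValidationError):
            oc.ContactEvent(label="bad", mode=Mode.PLATFORM)  # no duration
        with pytest.raises(oc.ValidationError):  # on-site must be in person
            oc.ContactEvent(label="bad", mode=Mode.TELEPHONE,
                            duration_minutes=10, on_site=True)


class TestAggregation:
    def test_published_patient_subtotal(self):
        """Patient items 5 504 + 1 204 + 1 445 + 1 100 aggregate to 9 253."""
        items = [
            oc.CostItem(Domain.PATIENT, Category.CONTACTS, 5504.0),
            oc.CostItem(Domain.PATIENT, Category.ADMINISTRATION, 1204.0),
            oc.CostItem(Domain.PATIENT, Category.TRANSPORTATION, 1445.0),
            oc.CostItem(Domain.PATIENT, Category.DIRECT_FEES, 1100.0),
        ]
        breakdown = oc.aggregate_breakdown(items)
        assert breakdown.subtotal_patient == pytest.approx(9253.0)
        assert breakdown.total == pytest.approx(9253.0)

    def test_single_item_identity(self):
        items = [oc.CostItem(Domain.OTHER, Category.EMISSIONS, 59.0)]
        breakdown = oc.aggregate_breakdown(items)
        assert breakdown.subtotal_other == 59.0
        assert breakdown.total == 59.0

    def test_empty_inventory(self):
        breakdown = oc.aggregate_breakdown([])
        assert breakdown.total == 0.0
        assert (breakdown.subtotal_system, breakdown.subtotal_patient,
                breakdown.subtotal_other) == (0.0, 0.0, 0.0)

    def test_stable_ordering(self):
        items = [
            oc.CostItem(Domain.OTHER, Category.EMISSIONS, 1.0),
            oc.CostItem(Domain.SYSTEM, Category.TRAINING, 2.0),
            oc.CostItem(Domain.SYSTEM, Category.CONTACTS, 3.0),
            oc.CostItem(Domain.PATIENT, Category.DIRECT_FEES, 4.0),
        ]
        breakdown = oc.aggregate_breakdown(items)
        keys = [(it.domain, it.category) for it in breakdown.items]
        assert keys == [(Domain.SYSTEM, Category.CONTACTS),
                        (Domain.SYSTEM, Category.TRAINING),
                        (Domain.PATIENT, Category.DIRECT_FEES),
                        (Domain.OTHER, Category.EMISSIONS)]

    def test_inconsistent_item_rejected(self):
        with pytest.raises(oc.ValidationError):
            oc.CostItem(Domain.SYSTEM, Category.CONTACTS, total=100.0,
                        quantity_hours=2.0, unit_value=200.0)


class TestCostModel:
    def test_fixture_line_items_match_published_table(self, ctx, boa, ja):
        expected = {
            "BOA": {(Domain.SYSTEM, Category.CONTACTS): 619,
                    (Domain.SYSTEM, Category.TRAINING): 30,
                    (Domain.PATIENT, Category.CONTACTS): 5504,
                    (Domain.PATIENT, Category.ADMINISTRATION): 1204,
                    (Domain.PATIENT, Category.TRANSPORTATION): 1445,
                    (Domain.PATIENT, Category.DIRECT_FEES): 1100,
                    (Domain.OTHER, Category.EMISSIONS): 59},
            "Joint Academy": {(Domain.SYSTEM, Category.CONTACTS): 145,
                              (Domain.SYSTEM, Category.TRAINING): 11,
                              (Domain.PATIENT, Category.CONTACTS): 716,
                              (Domain.PATIENT, Category.ADMINISTRATION): 195,
                              (Domain.PATIENT, Category.DIRECT_FEES): 1100},
        }
        for spec in (boa, ja):
            breakdown = oc.cost_model(spec, ctx)
            got = {(it.domain, it.category): oc.round_sek(it.total)
                   for it in breakdown.items}
            for key, value in expected[spec.name].items():
                assert got[key] == value, (spec.name, key)

    def test_fixture_subtotals_and_totals(self, ctx, boa, ja):
        b = oc.cost_model(boa, ctx)
        j = oc.cost_model(ja, ctx)
        assert oc.round_sek(b.subtotal_system) == 1299
        assert oc.round_sek(b.subtotal_patient) == 9253
        assert oc.round_sek(b.subtotal_other) == 59
        assert oc.round_sek(b.total) == 10611
        assert oc.round_sek(j.subtotal_system) == 766
        assert oc.round_sek(j.subtotal_patient) == 2010
        assert j.subtotal_other == 0.0
        assert oc.round_sek(j.total) == 2776

    def test_admin_row_merges_support(self, ctx, boa, ja):
        """The published Administration line includes stand-by support."""
        for spec, expected in ((boa, 651), (ja, 610)):
            breakdown = oc.cost_model(spec, ctx)
            admin = sum(it.total for it in breakdown.items
                        if it.domain is Domain.SYSTEM and it.category in
                        (Category.ADMINISTRATION, Category.TECHNICAL_SUPPORT))
            assert oc.round_sek(admin) == expected

    def test_zero_wage_context_leaves_only_fixed_fees(self, ja):
        ctx = oc.ValuationContext(provider_gross_hourly_wage=0.0,
                                  population_gross_hourly_wage=0.0)
        spec = oc.CareModelSpec(
            name=ja.name, contacts=ja.contacts, facility_based=False,
            admin_system_hours=ja.admin_system_hours,
            admin_patient_hours=ja.admin_patient_hours,
            training_hours_per_provider=ja.training_hours_per_provider,
            episodes_per_provider=ja.episodes_per_provider)
        breakdown = oc.cost_model(spec, ctx)
        assert breakdown.total == ctx.user_fee_ceiling

    def test_digital_model_has_no_transport_or_emission_items(self, ctx, ja):
        breakdown = oc.cost_model(ja, ctx)
        categories = {it.category for it in breakdown.items}
        assert Category.TRANSPORTATION not in categories
        assert Category.EMISSIONS not in categories

    def test_rounding_is_half_up_presentation_only(self):
        assert oc.round_sek(142.5) == 143
        assert oc.round_sek(8705.55) == 8706
        assert oc.round_sek(0.49999) == 0
        with pytest.raises(oc.ValidationError):
            oc.round_sek(math.nan)
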