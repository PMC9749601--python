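"""Coding, money partitioning and allocation rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutricost.allocation import (
    AllocationError,
    CodingRules,
    ScopeRule,
    TimeAllocationProfile,
    UnresolvedEntriesError,
    allocate_personnel,
    allocate_shared,
    allocate_to_arms,
    assign_codes,
    classify_stage,
    map_typology,
    partition_money,
)
from nutricost.calibration import default_coding_rules, default_time_profiles
from nutricost.codes import (
    Activity,
    Cadre,
    ComponentScope,
    InputCategory,
    Stage,
    Typology,
)
from nutricost.ledger import LedgerEntry


def entry(**kw):
    base = dict(
        entry_id="e1",
        month_index=10,
        amount_nominal=100.0,
        input_code=InputCategory.SUPPLIES,
    )
    base.update(kw)
    return LedgerEntry(**base)


# ---------------------------------------------------------------------------
# partitioning


@pytest.mark.parametrize(
    "amount,weights,expected",
    [
        (300.0, {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, {"a": 100.0, "b": 100.0, "c": 100.0}),
        (100.0, {"n": 0.60, "a": 0.25, "g": 0.15}, {"n": 60.0, "a": 25.0, "g": 15.0}),
        (0.0, {"a": 0.5, "b": 0.5}, {"a": 0.0, "b": 0.0}),
    ],
)
def test_allocate_shared_examples(amount, weights, expected):
    assert allocate_shared(amount, weights) == pytest.approx(expected)


def test_allocate_shared_penny_conserved():
    out = allocate_shared(0.01, {"a": 0.5, "b": 0.5})
    assert sum(out.values()) == pytest.approx(0.01, abs=1e-12)
    assert sorted(out.values()) == pytest.approx([0.0, 0.01])


def test_allocate_shared_rejects_bad_weights():
    with pytest.raises(AllocationError):
        allocate_shared(100.0, {})
    with pytest.raises(AllocationError):
        allocate_shared(100.0, {"a": 0.7, "b": 0.7})
    with pytest.raises(AllocationError):
        allocate_shared(-5.0, {"a": 1.0})


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    amount=st.floats(min_value=0.0, max_value=1e7, allow_nan=False),
    raw=st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=1, max_size=8),
)
def test_partition_conserves_and_stays_nonnegative(amount, raw):
    total = sum(raw)
    weights = {i: w / total for i, w in enumerate(raw)}
    out = partition_money(amount, weights)
    assert sum(out.values()) == pytest.approx(amount, abs=1e-6)
    assert all(v >= -1e-12 for v in out.values())


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    amount=st.floats(min_value=0.0, max_value=1e5, allow_nan=False),
    k=st.integers(min_value=2, max_value=20),
)
def test_partition_homogeneous_up_to_rounding(amount, k):
    weights = {"x": 0.6, "y": 0.3, "z": 0.1}
    small = partition_money(amount, weights)
    big = partition_money(k * amount, weights)
    for key in weights:
        assert big[key] == pytest.approx(k * small[key], abs=0.01 * (k + 1))


# ---------------------------------------------------------------------------
# coding


def test_assign_codes_hint_passthrough_and_startup():
    coded = assign_codes(
        [entry(month_index=2, activity_hint=Activity.TRAINING)], CodingRules()
    )
    assert coded[0].activity is Activity.TRAINING
    assert coded[0].stage is Stage.START_UP


def test_assign_codes_flags_cadre_for_time_share():
    coded = assign_codes(
        [entry(cadre=Cadre.PK, input_code=InputCategory.PERSONNEL_HIRED)], CodingRules()
    )
    assert coded[0].needs_time_share
    assert coded[0].activity is None


def test_assign_codes_input_default_rule():
    rules = CodingRules(
        input_defaults={InputCategory.OVERHEAD: Activity.INDIRECT_OVERHEAD}
    )
    coded = assign_codes([entry(input_code=InputCategory.OVERHEAD)], rules)
    assert coded[0].activity is Activity.INDIRECT_OVERHEAD
    assert coded[0].stage is Stage.RECURRENT


def test_assign_codes_keyword_rule():
    coded = assign_codes(
        [entry(description="Quarterly monitoring survey, Rangpur")],
        default_coding_rules(),
    )
    assert coded[0].activity is Activity.MONITORING_EVALUATION


def test_assign_codes_rejects_unresolvable_with_ids():
    entries = [
        entry(entry_id="bad-1", input_code=InputCategory.EQUIPMENT, description="???"),
        entry(entry_id="ok", activity_hint=Activity.TRAINING),
    ]
    with pytest.raises(UnresolvedEntriesError) as exc:
        assign_codes(entries, CodingRules())
    assert exc.value.entry_ids == ["bad-1"]


@pytest.mark.parametrize(
    "activity,month,stage",
    [
        (Activity.PLANNING_MICROPLANNING, 3, Stage.START_UP),
        (Activity.PLANNING_MICROPLANNING, 6, Stage.RECURRENT),
        # recurring work in the start-up months stays recurrent
        (Activity.HOME_VISITS_NUTRITION_GENDER, 2, Stage.RECURRENT),
        (Activity.MONITORING_EVALUATION, 0, Stage.RECURRENT),
        (Activity.TRAINING, 5, Stage.START_UP),
    ],
)
def test_stage_classification(activity, month, stage):
    assert classify_stage(activity, month) is stage


# ---------------------------------------------------------------------------
# personnel time shares


def test_allocate_personnel_pk_shares():
    out = allocate_personnel(100.0, default_time_profiles()[Cadre.PK])
    assert out[Activity.HOME_VISITS_NUTRITION_GENDER] == pytest.approx(80.0)
    assert out[Activity.TRAINING] == pytest.approx(10.0)
    assert out[Activity.PLANNING_MICROPLANNING] == pytest.approx(5.0)
    assert out[Activity.INTEGRATION_COORDINATION] == pytest.approx(5.0)


def test_allocate_personnel_part_time_dm():
    profile = TimeAllocationProfile(
        cadre=Cadre.DM,
        fte_share_on_programme=0.30,
        activity_shares={Activity.SITE_SUPERVISION: 1.0},
    )
    out = allocate_personnel(1000.0, profile)
    assert out == {Activity.SITE_SUPERVISION: pytest.approx(300.0)}


def test_allocate_personnel_zero_pool():
    out = allocate_personnel(0.0, default_time_profiles()[Cadre.PK])
    assert all(v == 0.0 for v in out.values())


def test_time_profile_rejects_bad_shares():
    with pytest.raises(ValueError):
        TimeAllocationProfile(
            cadre=Cadre.PK,
            fte_share_on_programme=1.0,
            activity_shares={Activity.TRAINING: 0.6, Activity.MANAGEMENT: 0.6},
        )


# ---------------------------------------------------------------------------
# arm allocation


EQ_HH = {2: 1260, 3: 1260, 4: 1260}


@pytest.mark.parametrize(
    "amount,scope,expected",
    [
        (300.0, ComponentScope.NUTRITION, {2: 100.0, 3: 100.0, 4: 100.0}),
        (200.0, ComponentScope.AGRICULTURE, {3: 100.0, 4: 100.0}),
        (50.0, ComponentScope.GENDER, {4: 50.0}),
        (300.0, ComponentScope.PLATFORM_WIDE, {2: 100.0, 3: 100.0, 4: 100.0}),
    ],
)
def test_allocate_to_arms_component_eligibility(amount, scope, expected):
    assert allocate_to_arms(amount, scope, EQ_HH) == pytest.approx(expected)


def test_allocate_to_arms_proportional_to_households():
    out = allocate_to_arms(300.0, ComponentScope.AGRICULTURE, {2: 500, 3: 1000, 4: 2000})
    assert out == pytest.approx({3: 100.0, 4: 200.0})


def test_allocate_to_arms_rejects_empty_eligible_set():
    with pytest.raises(AllocationError):
        allocate_to_arms(10.0, ComponentScope.GENDER, {2: 1260, 3: 1260})


# ---------------------------------------------------------------------------
# typology


def test_map_typology_direct_and_split():
    shared = {Typology.SUPPLY: 0.5, Typology.DEMAND: 0.3, Typology.ENABLING_ENVIRONMENT: 0.2}
    assert map_typology(Activity.HOME_VISITS_AGRICULTURE, shared) == {Typology.SUPPLY: 1.0}
    hvn = map_typology(Activity.HOME_VISITS_NUTRITION_GENDER, shared, 0.8)
    assert hvn == pytest.approx(
        {Typology.DEMAND: 0.8, Typology.ENABLING_ENVIRONMENT: 0.2}
    )
    assert map_typology(Activity.MANAGEMENT, shared) == pytest.approx(shared)


def test_map_typology_total_over_closed_set():
    shared = {Typology.SUPPLY: 0.2, Typology.DEMAND: 0.35, Typology.ENABLING_ENVIRONMENT: 0.45}
    for act in Activity:
        weights = map_typology(act, shared)
        assert sum(weights.values()) == pytest.approx(1.0)


def test_scope_rule_validates_sums():
    with pytest.raises(ValueError):
        ScopeRule(residual_shares={ComponentScope.NUTRITION: 0.5})
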