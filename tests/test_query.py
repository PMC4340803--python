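"""Query-engine semantics: filtering, partitions, intervals, grouping,
retrieval, implication probability and the instrumentation contract."""

import numpy as np
import pytest

from medmod import (
    ComparisonCondition,
    GroupingDef,
    IntervalDef,
    PartitionCondition,
    Query,
    QueryArgumentError,
    ResolutionError,
    Retrieval,
    SliceAggregateCondition,
    TypeMismatchError,
    apply_query,
    attach_intervals,
    compute_intervals,
    evaluate_comparison,
    evaluate_partition,
    evaluate_slice_aggregate,
    group_slices,
    implication_probability,
    instance_table,
    retrieve_aggregate,
)
from medmod.query import InspectionCounter
from medmod.simulator import (
    ASSIGN_PROCEDURE,
    EXECUTE_PROCEDURE,
    PATIENT_ENTERS,
    SET_DIAGNOSIS,
)

from . import _oracle
from .conftest import build_dataset, random_conditions, random_dataset


def diag(value, op="eq"):
    return ComparisonCondition(SET_DIAGNOSIS, "diagnosis", op, value)


# -- comparison conditions -------------------------------------------------


def test_comparison_keeps_whole_slices_containing_a_match(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [
                (PATIENT_ENTERS, 0, 1, {"age": 5}),
                (SET_DIAGNOSIS, 2, 1, {"diagnosis": "Chickenpox"}),
                (EXECUTE_PROCEDURE, 3, 1, {"cost": 80.0}),
            ],
            "S2": [
                (PATIENT_ENTERS, 0, 1, {"age": 40}),
                (SET_DIAGNOSIS, 2, 1, {"diagnosis": "Stroke"}),
            ],
            "S3": [(PATIENT_ENTERS, 0, 1, {"age": 70})],
        },
    )
    out = evaluate_comparison(ds, diag("Chickenpox"))
    assert out.slice_ids == ["S1"]
    assert len(out.get_slice("S1").instances) == 3  # all instances retained


def test_overly_large_age_threshold_empties_a_pediatric_dataset(hospital):
    ds = build_dataset(
        hospital,
        {
            f"S{i}": [(PATIENT_ENTERS, 0, 1, {"age": age})]
            for i, age in enumerate([3, 6, 11, 18])
        },
    )
    assert evaluate_comparison(
        ds, ComparisonCondition(PATIENT_ENTERS, "age", "gt", 67)
    ).slice_ids == []


def test_unsatisfiable_two_term_conjunction_is_empty(hospital, small_sim):
    cond = ComparisonCondition(
        PATIENT_ENTERS, "age", "gt", 6, combine="and", op2="lt", value2=6
    )
    assert evaluate_comparison(small_sim, cond).slice_ids == []


def test_two_term_or_widens_the_match(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [(PATIENT_ENTERS, 0, 1, {"age": 2})],
            "S2": [(PATIENT_ENTERS, 0, 1, {"age": 50})],
            "S3": [(PATIENT_ENTERS, 0, 1, {"age": 90})],
        },
    )
    cond = ComparisonCondition(
        PATIENT_ENTERS, "age", "lt", 6, combine="or", op2="gt", value2=80
    )
    assert evaluate_comparison(ds, cond).slice_ids == ["S1", "S3"]


def test_comparison_on_absent_value_is_false(hospital):
    ds = build_dataset(hospital, {"S1": [(PATIENT_ENTERS, 0, 1, {})]})
    assert evaluate_comparison(
        ds, ComparisonCondition(PATIENT_ENTERS, "age", "ge", 0)
    ).slice_ids == []


def test_string_operators_and_case_sensitivity(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [(PATIENT_ENTERS, 0, 1, {"surname": "Smith"})],
            "S2": [(PATIENT_ENTERS, 0, 1, {"surname": "smithers"})],
        },
    )
    begins = ComparisonCondition(PATIENT_ENTERS, "surname", "begins_with", "Smi")
    assert evaluate_comparison(ds, begins).slice_ids == ["S1"]
    contains = ComparisonCondition(PATIENT_ENTERS, "surname", "contains", "mit")
    assert evaluate_comparison(ds, contains).slice_ids == ["S1", "S2"]


def test_illegal_operator_and_unknown_names_raise(hospital, small_sim):
    with pytest.raises(TypeMismatchError):
        evaluate_comparison(
            small_sim, ComparisonCondition(PATIENT_ENTERS, "surname", "gt", "A")
        )
    with pytest.raises(TypeMismatchError):
        evaluate_comparison(small_sim, diag("NotALiteral"))
    with pytest.raises(ResolutionError):
        evaluate_comparison(
            small_sim, ComparisonCondition("No such step", "age", "eq", 1)
        )
    with pytest.raises(ResolutionError):
        evaluate_comparison(
            small_sim, ComparisonCondition(PATIENT_ENTERS, "ghost", "eq", 1)
        )


# -- slice aggregates ------------------------------------------------------


def cost_slice(hospital, sid, costs, extra=()):
    rows = [(PATIENT_ENTERS, 0, 1, {})]
    rows += [(EXECUTE_PROCEDURE, 2 + i, 1, {"cost": c}) for i, c in enumerate(costs)]
    rows += list(extra)
    return {sid: rows}


def test_average_cost_above_threshold_keeps_slice(hospital):
    ds = build_dataset(hospital, cost_slice(hospital, "S1", [80.0, 140.0]))
    cond = SliceAggregateCondition(
        EXECUTE_PROCEDURE, "average", "gt", 100, attribute="cost"
    )
    assert evaluate_slice_aggregate(ds, cond).slice_ids == ["S1"]  # avg 110


def test_count_happened_more_than_once_boundary(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [
                (PATIENT_ENTERS, 0, 1, {}),
                (SET_DIAGNOSIS, 2, 1, {"diagnosis": "Stroke"}),
            ],
            "S2": [
                (PATIENT_ENTERS, 0, 1, {}),
                (SET_DIAGNOSIS, 2, 1, {"diagnosis": "Stroke"}),
                (SET_DIAGNOSIS, 4, 1, {"diagnosis": "Stroke"}),
            ],
        },
    )
    cond = SliceAggregateCondition(SET_DIAGNOSIS, "count", "gt", 1)
    assert evaluate_slice_aggregate(ds, cond).slice_ids == ["S2"]


def test_aggregate_over_absent_activity_fails_the_slice(hospital):
    ds = build_dataset(hospital, {"S1": [(PATIENT_ENTERS, 0, 1, {})]})
    for cond in (
        SliceAggregateCondition(EXECUTE_PROCEDURE, "sum", "ge", 0, attribute="cost"),
        SliceAggregateCondition(EXECUTE_PROCEDURE, "count", "ge", 0),
    ):
        assert evaluate_slice_aggregate(ds, cond).slice_ids == []


def test_unvalued_instances_are_excluded_from_sum_and_average(hospital):
    ds = build_dataset(
        hospital,
        cost_slice(hospital, "S1", [100.0], extra=[(EXECUTE_PROCEDURE, 9, 1, {})]),
    )
    avg = SliceAggregateCondition(EXECUTE_PROCEDURE, "average", "eq", 100, attribute="cost")
    assert evaluate_slice_aggregate(ds, avg).slice_ids == ["S1"]
    # but Count sees both instances
    cnt = SliceAggregateCondition(EXECUTE_PROCEDURE, "count", "eq", 2)
    assert evaluate_slice_aggregate(ds, cnt).slice_ids == ["S1"]


# -- partitions ------------------------------------------------------------


def expenses_dataset(hospital, values, ids=None):
    ids = ids or [chr(ord("A") + i) for i in range(len(values))]
    return build_dataset(
        hospital,
        {
            sid: [(PATIENT_ENTERS, 0, 1, {"total_expenses": v})]
            for sid, v in zip(ids, values)
        },
    )


def test_top_k_with_tie_broken_by_slice_id(hospital):
    ds = expenses_dataset(hospital, [10.0, 50.0, 30.0, 50.0, 20.0])
    out = evaluate_partition(
        ds, PartitionCondition(PATIENT_ENTERS, "total_expenses", "top", 2)
    )
    assert sorted(out.slice_ids) == ["B", "D"]


def test_bottom_one_finds_the_minimum(hospital):
    ds = expenses_dataset(hospital, [10.0, 50.0, 30.0])
    out = evaluate_partition(
        ds, PartitionCondition(PATIENT_ENTERS, "total_expenses", "bottom", 1)
    )
    assert out.slice_ids == ["A"]


def test_k_saturation_returns_all_ranked_slices(hospital):
    ds = expenses_dataset(hospital, [10.0, 50.0, 30.0])
    out = evaluate_partition(
        ds, PartitionCondition(PATIENT_ENTERS, "total_expenses", "top", 50)
    )
    assert sorted(out.slice_ids) == ["A", "B", "C"]


def test_unvalued_slices_are_unranked(hospital):
    ds = build_dataset(
        hospital,
        {
            "A": [(PATIENT_ENTERS, 0, 1, {"total_expenses": 5.0})],
            "B": [(PATIENT_ENTERS, 0, 1, {})],
        },
    )
    out = evaluate_partition(
        ds, PartitionCondition(PATIENT_ENTERS, "total_expenses", "top", 10)
    )
    assert out.slice_ids == ["A"]


def test_k_out_of_range_is_an_argument_error(hospital, small_sim):
    for k in (0, 101):
        with pytest.raises(QueryArgumentError):
            evaluate_partition(
                small_sim,
                PartitionCondition(PATIENT_ENTERS, "total_expenses", "top", k),
            )


def test_partition_streaming_matches_full_sort_on_random_data(hospital):
    rng = np.random.default_rng(5)
    for trial in range(40):
        n = int(rng.integers(1, 25))
        values = rng.uniform(0, 100, size=n).round(1)
        if trial % 3 == 0:  # inject ties
            values = np.repeat(values[: max(1, n // 2)], 2)[:n]
        ds = expenses_dataset(hospital, [float(v) for v in values],
                              ids=[f"S{i:03d}" for i in range(n)])
        for direction in ("top", "bottom"):
            k = int(rng.integers(1, 10))
            cond = PartitionCondition(PATIENT_ENTERS, "total_expenses", direction, k)
            got = set(evaluate_partition(ds, cond).slice_ids)
            assert got == _oracle.partition_slices(ds, cond)


# -- ordered pipelines -----------------------------------------------------


def test_identity_query_returns_input_and_raw_counts(hospital, small_sim):
    res = apply_query(small_sim, Query())
    assert res.dataset.slice_ids == small_sim.slice_ids
    for act in hospital.activities:
        raw = sum(len(s.of_activity(act.name)) for s in small_sim.slices)
        assert res.activity_counts[act.name] == raw


def test_sequential_conditions_intersect_at_slice_level(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [
                (PATIENT_ENTERS, 0, 1, {}),
                (SET_DIAGNOSIS, 1, 1, {"diagnosis": "Pneumonia"}),
                (SET_DIAGNOSIS, 3, 1, {"diagnosis": "Stroke"}),
            ],
            "S2": [
                (PATIENT_ENTERS, 0, 1, {}),
                (SET_DIAGNOSIS, 1, 1, {"diagnosis": "Pneumonia"}),
            ],
            "S3": [
                (PATIENT_ENTERS, 0, 1, {}),
                (SET_DIAGNOSIS, 1, 1, {"diagnosis": "Stroke"}),
            ],
        },
    )
    res = apply_query(ds, Query(conditions=[diag("Pneumonia"), diag("Stroke")]))
    assert res.dataset.slice_ids == ["S1"]


def test_disjoint_partitions_intersect_to_empty(hospital):
    ds = expenses_dataset(hospital, [1.0, 2.0, 3.0, 4.0])
    q = Query(
        partitions=[
            PartitionCondition(PATIENT_ENTERS, "total_expenses", "top", 2),
            PartitionCondition(PATIENT_ENTERS, "total_expenses", "bottom", 2),
        ]
    )
    assert apply_query(ds, q).dataset.slice_ids == []


def test_partitions_apply_after_comparisons(hospital):
    ds = build_dataset(
        hospital,
        {
            "A": [(PATIENT_ENTERS, 0, 1, {"age": 10, "total_expenses": 99.0})],
            "B": [(PATIENT_ENTERS, 0, 1, {"age": 80, "total_expenses": 5.0})],
            "C": [(PATIENT_ENTERS, 0, 1, {"age": 12, "total_expenses": 7.0})],
        },
    )
    q = Query(
        conditions=[ComparisonCondition(PATIENT_ENTERS, "age", "lt", 18)],
        partitions=[PartitionCondition(PATIENT_ENTERS, "total_expenses", "bottom", 1)],
    )
    # B has the global minimum but is filtered out first
    assert apply_query(ds, q).dataset.slice_ids == ["C"]


# -- intervals -------------------------------------------------------------


def interval_def(pairing=False):
    return IntervalDef(
        name="procedure_wait",
        start_activity=ASSIGN_PROCEDURE,
        end_activity=EXECUTE_PROCEDURE,
        pairing_start_attribute="procedure_code" if pairing else None,
        pairing_end_attribute="procedure_code" if pairing else None,
    )


def test_pairing_condition_matches_procedure_codes(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [
                (PATIENT_ENTERS, 0, 1, {}),
                (ASSIGN_PROCEDURE, 10, 0.1, {"procedure_code": "P012"}),
                (EXECUTE_PROCEDURE, 11, 0.5, {"procedure_code": "P047"}),
                (EXECUTE_PROCEDURE, 12.5, 0.5, {"procedure_code": "P012"}),
            ]
        },
    )
    out = compute_intervals(ds.slices[0], interval_def(pairing=True), hospital)
    assert out == [9000.0]  # 10:00 -> 12:30, matching codes only


def test_adjacent_pairing_without_condition(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [
                (PATIENT_ENTERS, 0, 1, {}),
                (ASSIGN_PROCEDURE, 9, 0.1, {}),
                (ASSIGN_PROCEDURE, 10, 0.1, {}),
                (EXECUTE_PROCEDURE, 9.5, 0.1, {}),
                (EXECUTE_PROCEDURE, 10.5, 0.1, {}),
            ]
        },
    )
    out = compute_intervals(ds.slices[0], interval_def(), hospital)
    assert out == [1800.0, 1800.0]


def test_coincident_endpoints_give_zero_duration(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [
                (PATIENT_ENTERS, 0, 1, {}),
                (ASSIGN_PROCEDURE, 9, 0.1, {}),
                (EXECUTE_PROCEDURE, 9, 0.1, {}),
            ]
        },
    )
    assert compute_intervals(ds.slices[0], interval_def(), hospital) == [0.0]


def test_intervals_match_enumeration_oracle_on_random_data(hospital):
    rng = np.random.default_rng(9)
    for _ in range(30):
        rows = [(PATIENT_ENTERS, 0, 1, {})]
        for _ in range(int(rng.integers(0, 6))):
            rows.append(
                (ASSIGN_PROCEDURE, float(rng.uniform(1, 48)), 0.1,
                 {"procedure_code": str(rng.choice(["P012", "P047"]))})
            )
        for _ in range(int(rng.integers(0, 6))):
            rows.append(
                (EXECUTE_PROCEDURE, float(rng.uniform(1, 48)), 0.1,
                 {"procedure_code": str(rng.choice(["P012", "P047"]))})
            )
        ds = build_dataset(hospital, {"S1": rows})
        for pairing in (False, True):
            idef = interval_def(pairing)
            assert compute_intervals(ds.slices[0], idef, hospital) == (
                _oracle.interval_durations(ds.slices[0], idef, hospital)
            )


def test_defined_interval_is_usable_in_conditions_and_never_negative(hospital, small_sim):
    withs = attach_intervals(small_sim, [interval_def(pairing=True)])
    assert "procedure_wait" in withs.derived_names
    for s in withs.slices:
        for v in s.instances[0].derived.get("procedure_wait", []):
            assert v >= 0.0
    cond = ComparisonCondition(PATIENT_ENTERS, "procedure_wait", "ge", 0.0)
    out = evaluate_comparison(withs, cond)
    expected = {
        s.slice_id for s in withs.slices if s.instances[0].derived["procedure_wait"]
    }
    assert set(out.slice_ids) == expected


# -- grouping --------------------------------------------------------------


def surname_ds(hospital, names):
    return build_dataset(
        hospital,
        {
            f"S{i}": [(PATIENT_ENTERS, i, 1, {"surname": n} if n else {})]
            for i, n in enumerate(names)
        },
    )


def test_grouping_merges_equal_keys(hospital):
    ds = surname_ds(hospital, ["Smith", "Jones", "Smith"])
    out = group_slices(ds, GroupingDef(PATIENT_ENTERS, "surname"))
    assert len(out.slices) == 2
    merged = out.get_slice("group:Smith")
    assert merged is not None and len(merged.instances) == 2


def test_distinct_keys_leave_dataset_isomorphic(hospital):
    ds = surname_ds(hospital, ["Smith", "Jones", "Osis"])
    out = group_slices(ds, GroupingDef(PATIENT_ENTERS, "surname"))
    assert out.slice_ids == ds.slice_ids


def test_unkeyed_slices_stay_singletons(hospital):
    ds = surname_ds(hospital, ["Smith", None, "Smith"])
    out = group_slices(ds, GroupingDef(PATIENT_ENTERS, "surname"))
    assert sorted(out.slice_ids) == ["S1", "group:Smith"]


def test_multi_key_slice_joins_exactly_one_group_by_earliest_instance(hospital):
    ds = build_dataset(
        hospital,
        {
            "S0": [
                (PATIENT_ENTERS, 5, 1, {"surname": "Jones"}),
                (PATIENT_ENTERS, 1, 1, {"surname": "Smith"}),
            ],
            "S1": [(PATIENT_ENTERS, 0, 1, {"surname": "Smith"})],
            "S2": [(PATIENT_ENTERS, 0, 1, {"surname": "Jones"})],
        },
    )
    out = group_slices(ds, GroupingDef(PATIENT_ENTERS, "surname"))
    smith = out.get_slice("group:Smith")
    assert len(smith.instances) == 3  # S0 keyed by its earliest instance
    assert out.get_slice("S2") is not None  # Jones group left a singleton
    all_ids = [i.instance_id for s in out.slices for i in s.instances]
    assert len(all_ids) == len(set(all_ids))  # disjointness preserved


def test_grouped_intervals_span_original_slices(hospital):
    ds = build_dataset(
        hospital,
        {
            "S0": [
                (PATIENT_ENTERS, 0, 1, {"surname": "Smith"}),
                (ASSIGN_PROCEDURE, 1, 0.1, {}),
            ],
            "S1": [
                (PATIENT_ENTERS, 100, 1, {"surname": "Smith"}),
                (EXECUTE_PROCEDURE, 101, 0.1, {}),
            ],
        },
    )
    q = Query(
        intervals=[interval_def()],
        grouping=GroupingDef(PATIENT_ENTERS, "surname"),
    )
    res = apply_query(ds, q)
    merged = res.dataset.get_slice("group:Smith")
    assert merged.instances[0].derived["procedure_wait"] == [100 * 3600.0]


# -- retrieval -------------------------------------------------------------


def test_count_sum_average_over_dataset(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [
                (PATIENT_ENTERS, 0, 1, {}),
                (EXECUTE_PROCEDURE, 1, 1, {"cost": 80.0}),
                (EXECUTE_PROCEDURE, 2, 1, {"cost": 140.0}),
            ],
            "S2": [
                (PATIENT_ENTERS, 0, 1, {}),
                (EXECUTE_PROCEDURE, 1, 1, {"cost": 100.0}),
            ],
        },
    )
    assert retrieve_aggregate(ds, EXECUTE_PROCEDURE, "count") == 3
    assert retrieve_aggregate(ds, EXECUTE_PROCEDURE, "sum", "cost") == 320.0
    assert retrieve_aggregate(ds, EXECUTE_PROCEDURE, "average", "cost") == pytest.approx(
        106.66666666666667
    )


def test_empty_aggregates_and_undefined_average(hospital):
    ds = build_dataset(hospital, {"S1": [(PATIENT_ENTERS, 0, 1, {})]})
    assert retrieve_aggregate(ds, EXECUTE_PROCEDURE, "count") == 0
    assert retrieve_aggregate(ds, EXECUTE_PROCEDURE, "sum", "cost") == 0.0
    assert retrieve_aggregate(ds, EXECUTE_PROCEDURE, "average", "cost") is None


def test_instance_table_shape_and_order(hospital, small_sim):
    table = instance_table(small_sim, EXECUTE_PROCEDURE)
    assert list(table.columns) == [
        "slice_id", "instance_id", "start_time", "end_time", "procedure_code", "cost",
    ]
    assert len(table) == retrieve_aggregate(small_sim, EXECUTE_PROCEDURE, "count")
    assert list(table["start_time"]) == sorted(table["start_time"])
    empty = instance_table(
        small_sim.subset([]), EXECUTE_PROCEDURE
    )
    assert len(empty) == 0 and list(empty.columns) == list(table.columns)


def test_rows_from_different_slices_carry_their_slice_ids(hospital):
    ds = build_dataset(
        hospital,
        {
            "S1": [(PATIENT_ENTERS, 0, 1, {"age": 1})],
            "S2": [(PATIENT_ENTERS, 1, 1, {"age": 2})],
        },
    )
    table = instance_table(ds, PATIENT_ENTERS)
    assert sorted(table["slice_id"]) == ["S1", "S2"]


# -- implication probability ----------------------------------------------


def test_implication_probability_counts_slices(hospital):
    spec = {}
    for i in range(4):
        rows = [
            (PATIENT_ENTERS, 0, 1, {}),
            (SET_DIAGNOSIS, 1, 1, {"diagnosis": "Pneumonia"}),
        ]
        if i == 0:
            rows.append((SET_DIAGNOSIS, 2, 1, {"diagnosis": "Stroke"}))
        spec[f"S{i}"] = rows
    spec["S9"] = [(PATIENT_ENTERS, 0, 1, {})]
    ds = build_dataset(hospital, spec)
    p = implication_probability(ds, diag("Pneumonia"), diag("Stroke"))
    assert p == 0.25


def test_implication_undefined_without_antecedent_matches(hospital, small_sim):
    impossible = ComparisonCondition(PATIENT_ENTERS, "age", "gt", 1000)
    assert implication_probability(small_sim, impossible, impossible) is None


def test_self_implication_is_one(hospital, small_sim):
    cond = diag("Influenza")
    if evaluate_comparison(small_sim, cond).slices:
        assert implication_probability(small_sim, cond, cond) == 1.0


# -- randomized oracle equivalence and instrumentation ---------------------


def test_every_filter_matches_bruteforce_on_random_datasets():
    rng = np.random.default_rng(2024)
    for seed in range(30):
        ds = random_dataset(seed)
        n = ds.n_instances
        for cond in random_conditions(rng):
            counter = InspectionCounter()
            if isinstance(cond, ComparisonCondition):
                got = evaluate_comparison(ds, cond, counter)
                expect = _oracle.comparison_slices(ds, cond)
                assert counter.total <= n
            elif isinstance(cond, SliceAggregateCondition):
                got = evaluate_slice_aggregate(ds, cond, counter)
                expect = _oracle.aggregate_slices(ds, cond)
                assert counter.total <= n
            else:
                got = evaluate_partition(ds, cond, counter)
                expect = _oracle.partition_slices(ds, cond)
                assert counter.total <= cond.k * n
            assert set(got.slice_ids) == expect, cond


def test_filters_are_monotone_and_idempotent():
    rng = np.random.default_rng(7)
    ds = random_dataset(13)
    for cond in random_conditions(rng):
        if isinstance(cond, ComparisonCondition):
            apply = lambda d: evaluate_comparison(d, cond)
        elif isinstance(cond, SliceAggregateCondition):
            apply = lambda d: evaluate_slice_aggregate(d, cond)
        else:
            apply = lambda d: evaluate_partition(d, cond)
        once = apply(ds)
        assert set(once.slice_ids) <= set(ds.slice_ids)
        assert apply(once).slice_ids == once.slice_ids


def test_condition_order_never_changes_the_final_slice_set():
    rng = np.random.default_rng(3)
    ds = random_dataset(17)
    conds = [
        c
        for c in random_conditions(rng)
        if isinstance(c, (ComparisonCondition, SliceAggregateCondition))
    ]
    baseline = set(apply_query(ds, Query(conditions=conds)).dataset.slice_ids)
    for _ in range(5):
        perm = [conds[i] for i in rng.permutation(len(conds))]
        assert set(apply_query(ds, Query(conditions=perm)).dataset.slice_ids) == baseline
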