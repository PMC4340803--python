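"""Shared fixtures: the demo hospital model, hand-built datasets, and a
random-condition generator used by the oracle-equivalence suites."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from medmod import (
    ComparisonCondition,
    Dataset,
    Instance,
    PartitionCondition,
    Slice,
    SliceAggregateCondition,
)
from medmod.simulator import (
    ASSIGN_PROCEDURE,
    D_CODES,
    EXECUTE_PROCEDURE,
    PATIENT_ENTERS,
    SET_DIAGNOSIS,
    SURNAMES,
    demo_config,
    demo_model,
    simulate,
)

EPOCH = datetime(2020, 1, 1, tzinfo=timezone.utc)


def at(hours: float) -> datetime:
    return EPOCH + timedelta(hours=hours)


@pytest.fixture(scope="session")
def hospital():
    return demo_model()


def build_dataset(model, spec) -> Dataset:
    """Hand-build a dataset from ``{slice_id: [(activity, start_h, dur_h,
    attrs), ...]}``; instance ids are ``<slice_id>-<ordinal>``."""
    slices = []
    for sid, insts in spec.items():
        rows = []
        for n, (activity, start_h, dur_h, attrs) in enumerate(insts):
            rows.append(
                Instance(
                    instance_id=f"{sid}-{n:02d}",
                    activity=activity,
                    slice_id=sid,
                    start_time=at(start_h),
                    end_time=None if dur_h is None else at(start_h + dur_h),
                    attributes=dict(attrs),
                )
            )
        slices.append(Slice(sid, rows))
    return Dataset(model, slices)


@pytest.fixture()
def small_sim(hospital):
    """A 30-slice simulated dataset, fixed seed."""
    return simulate(hospital, demo_config(n_slices=30, seed=11))


def random_dataset(seed: int) -> Dataset:
    """A small seeded simulated dataset (3..20 slices)."""
    n = 3 + seed % 18
    return simulate(demo_model(), demo_config(n_slices=n, seed=seed))


def random_conditions(rng: np.random.Generator):
    """One condition of every kind, with randomized operators/constants."""
    num_ops = ["eq", "ne", "gt", "lt", "ge", "le"]
    yield ComparisonCondition(
        SET_DIAGNOSIS, "diagnosis", rng.choice(["eq", "ne"]), rng.choice(D_CODES)
    )
    yield ComparisonCondition(
        PATIENT_ENTERS, "age", rng.choice(num_ops), int(rng.integers(0, 96))
    )
    combine = rng.choice(["and", "or"])
    yield ComparisonCondition(
        PATIENT_ENTERS,
        "age",
        rng.choice(num_ops),
        int(rng.integers(0, 96)),
        combine=combine,
        op2=rng.choice(num_ops),
        value2=int(rng.integers(0, 96)),
    )
    surname = SURNAMES[rng.integers(0, len(SURNAMES))]
    fragment = surname[: rng.integers(1, len(surname) + 1)]
    yield ComparisonCondition(
        PATIENT_ENTERS,
        "surname",
        rng.choice(["contains", "begins_with", "ends_with"]),
        fragment,
    )
    yield ComparisonCondition(
        SET_DIAGNOSIS, "count", rng.choice(num_ops), int(rng.integers(0, 6))
    )
    yield SliceAggregateCondition(
        EXECUTE_PROCEDURE,
        "sum",
        rng.choice(num_ops),
        float(rng.uniform(50, 1200)),
        attribute="cost",
    )
    yield SliceAggregateCondition(
        EXECUTE_PROCEDURE,
        "average",
        rng.choice(num_ops),
        float(rng.uniform(20, 250)),
        attribute="cost",
    )
    yield SliceAggregateCondition(
        ASSIGN_PROCEDURE, "count", rng.choice(num_ops), int(rng.integers(0, 8))
    )
    yield PartitionCondition(
        PATIENT_ENTERS, "total_expenses", "top", int(rng.integers(1, 8))
    )
    yield PartitionCondition(
        EXECUTE_PROCEDURE, "cost", "bottom", int(rng.integers(1, 8))
    )
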