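"""Shared fixtures: noise-free simulated courses and cycle-series builders."""

from __future__ import annotations

import pytest

from srbvkit.kinetics import (
    NeonateProfile,
    NoiseModel,
    PhototherapySchedule,
    default_kinetics,
    simulate_course,
)
from srbvkit.rvp import CourseSeries, PairedCycle

ZERO_NOISE = NoiseModel(tcb_cv=0.0, tsb_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def schedule() -> PhototherapySchedule:
    return PhototherapySchedule()


@pytest.fixture(scope="session")
def high_baseline_profile() -> NeonateProfile:
    """Moderately severe jaundice: composite baseline ~13 mg/dL."""
    return NeonateProfile("hb-001", "SITE-A", 4.0, 11.2, default_kinetics(11.2))


@pytest.fixture(scope="session")
def noise_free_course(high_baseline_profile, schedule):
    return simulate_course(high_baseline_profile, schedule, ZERO_NOISE)


def paired_readings(course, schedule):
    """Extract ((out...), (return...), pre) noise-free device readings."""
    tbl = {
        (e.phase, round(e.time_h, 6)): e.value
        for e in course.measurements
        if e.kind == "TBL_raw"
    }
    outs = [tbl[("out", round(schedule.session_end(i), 6))] for i in range(1, schedule.n_cycles + 1)]
    rets = [tbl[("return", round(schedule.break_end(i), 6))] for i in range(1, schedule.n_cycles + 1)]
    return outs, rets, tbl[("pre", 0.0)]


def series_from_course(course, schedule, neonate_id=None) -> CourseSeries:
    outs, rets, pre = paired_readings(course, schedule)
    cycles = tuple(
        PairedCycle(
            cycle_index=i,
            t_out=schedule.session_end(i),
            tbl_out=outs[i - 1],
            t_return=schedule.break_end(i),
            tbl_return=rets[i - 1],
        )
        for i in range(1, schedule.n_cycles + 1)
    )
    return CourseSeries(
        neonate_id=neonate_id or course.profile.neonate_id,
        site_id=course.profile.site_id,
        baseline_tbl=pre,
        cycles=cycles,
    )


def series_from_deltas(deltas, baseline=14.0, start_out=13.0, step=-0.5):
    """Build a course series realising the requested delta sequence."""
    cycles = []
    for i, d in enumerate(deltas, start=1):
        t_out = (i - 1) * (10.0 / 3.0) + 3.0
        out = start_out + (i - 1) * step
        cycles.append(
            PairedCycle(i, t_out, out, t_out + 1.0 / 3.0, out + d)
        )
    return CourseSeries("fab-001", "SITE-A", baseline, tuple(cycles))
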