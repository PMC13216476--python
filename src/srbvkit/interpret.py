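"""SRBV-adjusted interpretation of transcutaneous readings.

A deterministic first-match-wins rule cascade turns a course's latest
readings and its flip status into a clinical state with a recommendation
and a full rationale trace.  The cascade is ordered most-conservative
first:

1. Below 3 mg/dL the skin residual is negligible and the device reads
   serum — manage on the reading directly.
2. A still-positive break rebound means the cutaneous depot persists —
   continue therapy.
3. After the flip, trends are prioritised over absolute values: while the
   latest session-end reading is at or above the discharge threshold, or
   the post-flip decline is not monotone, keep monitoring the trend.
4. Flip reached, monotone decline, latest session-end reading below the
   discharge threshold — recovery confirmed, discharge eligible.
5. Otherwise the reading is an unresolved composite; since the composite
   bounds serum from above, treat it as a safe-side upper bound.

The discharge threshold defaults to 11 mg/dL (the study's end-of-treatment
objective) but is a parameter, not a universal cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .rvp import CourseSeries, RvpResult

__all__ = [
    "State",
    "Action",
    "InterpretationState",
    "Recommendation",
    "interpret_single",
    "interpret_course",
    "batch_interpret",
    "SERUM_EQUIVALENCE_LIMIT",
    "DISCHARGE_THRESHOLD",
]

#: Below this composite reading (mg/dL) the skin residual is negligible.
SERUM_EQUIVALENCE_LIMIT = 3.0

#: Default discharge threshold on the session-end reading (mg/dL).
DISCHARGE_THRESHOLD = 11.0

State = Literal[
    "SERUM_EQUIVALENT",
    "COMPOSITE_UNRESOLVED",
    "SRBV_PERSISTENT",
    "RVP_REACHED",
    "RECOVERY_CONFIRMED",
]

Action = Literal[
    "manage_on_tbl",
    "treat_as_upper_bound",
    "continue_therapy",
    "monitor_trend",
    "discharge_eligible",
]

#: Conservatism ordering (most conservative first) used by safety checks.
ACTION_CONSERVATISM: tuple[Action, ...] = (
    "continue_therapy",
    "treat_as_upper_bound",
    "monitor_trend",
    "manage_on_tbl",
    "discharge_eligible",
)


@dataclass(frozen=True)
class InterpretationState:
    state: State
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("rationale must be non-empty")


@dataclass(frozen=True)
class Recommendation:
    action: Action
    thresholds_used: tuple[tuple[str, float], ...]


def interpret_single(tbl: float) -> tuple[InterpretationState, Recommendation]:
    """Classify a lone calibrated reading with no serial history."""
    if tbl <= 0:
        raise ValueError("tbl must be > 0")
    thresholds = (("serum_equivalence", SERUM_EQUIVALENCE_LIMIT),)
    if tbl < SERUM_EQUIVALENCE_LIMIT:
        return (
            InterpretationState(
                "SERUM_EQUIVALENT",
                (f"single_reading_lt3: tbl={tbl:.2f} < {SERUM_EQUIVALENCE_LIMIT}",),
            ),
            Recommendation("manage_on_tbl", thresholds),
        )
    return (
        InterpretationState(
            "COMPOSITE_UNRESOLVED",
            (
                f"single_reading_ge3: tbl={tbl:.2f} >= {SERUM_EQUIVALENCE_LIMIT}; "
                "composite includes a variable skin residual and bounds serum from above",
            ),
        ),
        Recommendation("treat_as_upper_bound", thresholds),
    )


def interpret_course(
    series: CourseSeries,
    rvp: RvpResult,
    discharge_threshold: float = DISCHARGE_THRESHOLD,
) -> tuple[InterpretationState, Recommendation]:
    """Run the rule cascade on a course and its flip result."""
    if not series.cycles:
        raise ValueError("series must have at least one cycle")
    if rvp.neonate_id != series.neonate_id:
        raise ValueError(
            f"series/rvp mismatch: {series.neonate_id!r} vs {rvp.neonate_id!r}"
        )
    last = series.cycles[-1]
    latest_return = last.tbl_return
    latest_out = last.tbl_out
    latest_delta = last.delta
    detected = rvp.status == "rvp_detected"
    thresholds = (
        ("serum_equivalence", SERUM_EQUIVALENCE_LIMIT),
        ("discharge", discharge_threshold),
    )
    trace: list[str] = []

    trace.append(
        f"rule1_serum_equivalent: latest_return={latest_return:.2f} "
        f"{'<' if latest_return < SERUM_EQUIVALENCE_LIMIT else '>='} {SERUM_EQUIVALENCE_LIMIT}"
    )
    if latest_return < SERUM_EQUIVALENCE_LIMIT:
        return (
            InterpretationState("SERUM_EQUIVALENT", tuple(trace)),
            Recommendation("manage_on_tbl", thresholds),
        )

    trace.append(
        f"rule2_srbv_persistent: rvp={rvp.status}, latest_delta={latest_delta:+.2f}"
    )
    if not detected and latest_delta > 0:
        return (
            InterpretationState("SRBV_PERSISTENT", tuple(trace)),
            Recommendation("continue_therapy", thresholds),
        )

    trace.append(
        "rule3_rvp_reached: "
        f"rvp={rvp.status}, latest_out={latest_out:.2f}, "
        f"post_rvp_monotone={rvp.post_rvp_monotone}"
    )
    if detected and (latest_out >= discharge_threshold or not rvp.post_rvp_monotone):
        return (
            InterpretationState("RVP_REACHED", tuple(trace)),
            Recommendation("monitor_trend", thresholds),
        )

    trace.append(
        "rule4_recovery_confirmed: "
        f"rvp={rvp.status}, monotone={rvp.post_rvp_monotone}, "
        f"latest_out={latest_out:.2f} vs discharge={discharge_threshold}"
    )
    if detected and rvp.post_rvp_monotone and latest_out < discharge_threshold:
        return (
            InterpretationState("RECOVERY_CONFIRMED", tuple(trace)),
            Recommendation("discharge_eligible", thresholds),
        )

    trace.append("rule5_fallthrough: composite unresolved; reading bounds serum from above")
    return (
        InterpretationState("COMPOSITE_UNRESOLVED", tuple(trace)),
        Recommendation("treat_as_upper_bound", thresholds),
    )


def batch_interpret(
    courses: Sequence[CourseSeries],
    rvp_results: Sequence[RvpResult],
    discharge_threshold: float = DISCHARGE_THRESHOLD,
) -> pd.DataFrame:
    """Interpret every course; one row per neonate, ordered by id."""
    if len(courses) != len(rvp_results):
        raise ValueError("courses and rvp_results must align")
    ids = [c.neonate_id for c in courses]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate neonate_id: {dupes}")
    by_id = {r.neonate_id: r for r in rvp_results}
    rows = []
    for c in sorted(courses, key=lambda c: c.neonate_id):
        state, rec = interpret_course(c, by_id[c.neonate_id], discharge_threshold)
        rows.append(
            {
                "neonate_id": c.neonate_id,
                "site_id": c.site_id,
                "state": state.state,
                "action": rec.action,
                "rationale": " | ".join(state.rationale),
            }
        )
    cols = ["neonate_id", "site_id", "state", "action", "rationale"]
    return pd.DataFrame(rows, columns=cols)
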