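"""Recovery value flip (RVP) detection from serial paired session-boundary
readings.

Each phototherapy cycle yields a paired reading: TBL-out at the end of the
light session and TBL-return at the end of the following break.  Early in
treatment the break-time rebound makes the delta (return minus out)
positive; once the cutaneous depot and the production transient are
depleted the delta turns negative and stays negative — the recovery value
flip, a non-invasive marker that sustained clearance now dominates.

"Consistently lower" is operationalised as the first negative delta that
starts a run of at least two consecutive negative deltas (or is the final
cycle); a single negative excursion does not flip.  Courses with baseline
at or below 9 mg/dL are classified ineligible rather than dropped, since
the flip is attenuated when the skin depot is small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedCycle",
    "CourseSeries",
    "RvpResult",
    "RvpStatus",
    "SiteSummary",
    "compute_deltas",
    "detect_rvp",
    "decline_rate",
    "summarise_site",
    "series_from_measurements",
    "RVP_BASELINE_ELIGIBILITY",
    "MIN_ADEQUATE_CYCLES",
]

#: Baseline composite reading (mg/dL) strictly above which a course is
#: eligible for flip detection.
RVP_BASELINE_ELIGIBILITY = 9.0

#: Minimum number of paired cycles regarded as adequate serial data.
MIN_ADEQUATE_CYCLES = 3

RvpStatus = Literal[
    "rvp_detected",
    "no_flip",
    "immediate_decline",
    "ineligible_low_baseline",
    "insufficient_data",
]

DeclineMethod = Literal["ols", "endpoint"]


@dataclass(frozen=True)
class PairedCycle:
    """One cycle's (TBL-out, TBL-return) reading pair, calibrated mg/dL."""

    cycle_index: int  # 1-based
    t_out: float
    tbl_out: float
    t_return: float
    tbl_return: float

    def __post_init__(self) -> None:
        if self.t_return <= self.t_out:
            raise ValueError("t_return must be > t_out")
        if self.cycle_index < 1:
            raise ValueError("cycle_index is 1-based")

    @property
    def delta(self) -> float:
        return self.tbl_return - self.tbl_out


@dataclass(frozen=True)
class CourseSeries:
    neonate_id: str
    site_id: str
    baseline_tbl: float
    cycles: tuple[PairedCycle, ...]
    tsb_anchors: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline_tbl <= 0:
            raise ValueError("baseline_tbl must be > 0")
        times = [c.t_out for c in self.cycles]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("cycles must be strictly ordered in time")


@dataclass(frozen=True)
class RvpResult:
    neonate_id: str
    status: RvpStatus
    rvp_cycle: int | None
    deltas: tuple[float, ...]
    post_rvp_monotone: bool

    def __post_init__(self) -> None:
        if (self.status == "rvp_detected") != (self.rvp_cycle is not None):
            raise ValueError("rvp_cycle must be present iff status is rvp_detected")
        if self.rvp_cycle is not None and self.rvp_cycle < 2:
            raise ValueError("a detected flip is at cycle >= 2")


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    n_patients: int
    mean_age_days: float | None
    sd_age_days: float | None
    mean_pretreatment_tbl: float
    tbl_range: tuple[float, float]
    mean_decline_rate: float
    rvp_observed_pct: float | None
    n_eligible: int


def compute_deltas(series: CourseSeries) -> list[float]:
    """Return-minus-out difference for each cycle, in cycle order."""
    if not series.cycles:
        raise ValueError("series has no cycles")
    return [c.delta for c in series.cycles]


def detect_rvp(series: CourseSeries) -> RvpResult:
    """Locate the recovery value flip in one course, if present.

    The flip cycle is the smallest j >= 2 whose predecessor delta is
    non-negative (zero counts as pre-flip: the flip is strictly
    return < out) and whose own negative delta opens a run of >= 2
    consecutive negatives or is the terminal cycle.
    """
    deltas = tuple(compute_deltas(series))
    n = len(deltas)

    def result(status: RvpStatus, cycle: int | None) -> RvpResult:
        if cycle is None:
            monotone = False
        else:
            outs = [c.tbl_out for c in series.cycles[cycle - 1 :]]
            monotone = all(b <= a + 1e-12 for a, b in zip(outs, outs[1:]))
        return RvpResult(series.neonate_id, status, cycle, deltas, monotone)

    if series.baseline_tbl <= RVP_BASELINE_ELIGIBILITY:
        return result("ineligible_low_baseline", None)
    if n < MIN_ADEQUATE_CYCLES:
        return result("insufficient_data", None)
    if all(d < 0 for d in deltas):
        return result("immediate_decline", None)
    for j in range(2, n + 1):
        if deltas[j - 2] >= 0 and deltas[j - 1] < 0:
            is_terminal = j == n
            persistent = j < n and deltas[j] < 0
            if is_terminal or persistent:
                return result("rvp_detected", j)
    return result("no_flip", None)


def decline_rate(series: CourseSeries, method: DeclineMethod = "ols") -> float:
    """Course-level composite decline rate (mg/dL/h) from TBL-out readings.

    The least-squares slope of TBL-out against time is negated so decline
    is positive; a net rise comes back negative.  ``endpoint`` uses the
    first/last pair instead.
    """
    if len(series.cycles) < 2:
        raise ValueError("need >= 2 TBL-out readings for a decline rate")
    t = np.array([c.t_out for c in series.cycles])
    y = np.array([c.tbl_out for c in series.cycles])
    if np.ptp(t) == 0:
        raise ValueError("all TBL-out readings share one time")
    if method == "endpoint":
        return float(-(y[-1] - y[0]) / (t[-1] - t[0]))
    slope = np.polyfit(t, y, 1)[0]
    return float(-slope)


def summarise_site(
    series_list: Sequence[CourseSeries],
    rvp_results: Sequence[RvpResult],
    ages_days: Sequence[float] | None = None,
) -> SiteSummary:
    """Aggregate one site's courses into a published-style summary row.

    The flip percentage's denominator is the auditable count of eligible
    courses (baseline above 9 mg/dL) with adequate serial data.  Postnatal
    ages are not part of the reading series, so they are passed alongside
    when available (one per course, same order).
    """
    if not series_list:
        raise ValueError("empty site")
    sites = {s.site_id for s in series_list}
    if len(sites) != 1:
        raise ValueError(f"series from multiple sites: {sorted(sites)}")
    by_id = {r.neonate_id: r for r in rvp_results}

    baselines = [s.baseline_tbl for s in series_list]
    rates = [decline_rate(s) for s in series_list if len(s.cycles) >= 2]
    if ages_days is not None and len(ages_days) != len(series_list):
        raise ValueError("ages_days must align with series_list")
    mean_age = float(np.mean(ages_days)) if ages_days is not None else None
    sd_age = (
        float(np.std(ages_days, ddof=1))
        if ages_days is not None and len(ages_days) > 1
        else (0.0 if ages_days is not None else None)
    )

    eligible = [
        s
        for s in series_list
        if s.baseline_tbl > RVP_BASELINE_ELIGIBILITY
        and len(s.cycles) >= MIN_ADEQUATE_CYCLES
    ]
    n_detected = sum(
        1 for s in eligible if by_id[s.neonate_id].status == "rvp_detected"
    )
    pct = 100.0 * n_detected / len(eligible) if eligible else None

    return SiteSummary(
        site_id=sites.pop(),
        n_patients=len(series_list),
        mean_age_days=mean_age,
        sd_age_days=sd_age,
        mean_pretreatment_tbl=float(np.mean(baselines)),
        tbl_range=(float(np.min(baselines)), float(np.max(baselines))),
        mean_decline_rate=float(np.mean(rates)) if rates else float("nan"),
        rvp_observed_pct=pct,
        n_eligible=len(eligible),
    )


def series_from_measurements(measurements: pd.DataFrame) -> list[CourseSeries]:
    """Assemble per-course cycle series from a long-format reading table.

    Expects calibrated device readings with columns (neonate_id, site_id,
    time_h, phase, value_mg_dl) where phase is pre/out/return; laboratory
    rows (kind == "TSB") may be present and become stage anchors.  Cycles
    are paired by order: the i-th out reading with the i-th return reading
    that follows it; a trailing unmatched out reading is dropped.
    """
    required = {"neonate_id", "site_id", "time_h", "phase", "value_mg_dl"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    out: list[CourseSeries] = []
    df = measurements
    if "kind" in df.columns:
        tbl_df = df[df["kind"] != "TSB"]
        tsb_df = df[df["kind"] == "TSB"]
    else:
        tbl_df = df
        tsb_df = df.iloc[0:0]
    for (neonate_id, site_id), grp in tbl_df.groupby(
        ["neonate_id", "site_id"], sort=True
    ):
        grp = grp.sort_values("time_h")
        pre = grp[grp["phase"] == "pre"]
        if pre.empty:
            raise ValueError(f"{neonate_id}: no pre-treatment reading")
        baseline = float(pre["value_mg_dl"].iloc[0])
        outs = grp[grp["phase"] == "out"]
        rets = grp[grp["phase"] == "return"]
        cycles = []
        for i, o in enumerate(outs.itertuples()):
            if i >= len(rets):
                break  # trailing out reading without a return partner
            r = rets.iloc[i]
            if float(r["time_h"]) <= float(o.time_h):
                raise ValueError(f"{neonate_id}: unordered out/return readings")
            cycles.append(
                PairedCycle(
                    cycle_index=i + 1,
                    t_out=float(o.time_h),
                    tbl_out=float(o.value_mg_dl),
                    t_return=float(r["time_h"]),
                    tbl_return=float(r["value_mg_dl"]),
                )
            )
        anchors = tuple(
            (str(row.phase), float(row.value_mg_dl))
            for row in tsb_df[tsb_df["neonate_id"] == neonate_id].itertuples()
        )
        out.append(
            CourseSeries(
                neonate_id=str(neonate_id),
                site_id=str(site_id),
                baseline_tbl=baseline,
                cycles=tuple(cycles),
                tsb_anchors=anchors,
            )
        )
    return out
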