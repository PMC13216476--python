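"""Skin residual bilirubin volume (SRBV) estimation from paired readings.

The composite transcutaneous reading decomposes additively,
``TBL = TSB + SRBV``, so a paired calibrated device reading and
laboratory serum value yield the skin residual directly by subtraction.
Its fractional contribution ``SRBV / TBL`` is summarised per centre by
severity band and treatment stage, with an unweighted across-site average
row, mirroring how the field cohort was reported.

A negative residual (device below laboratory) contradicts the additive
model's observed regime and is retained and flagged as a potential
artefact but excluded from fraction summaries, with an audit count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Stage",
    "Band",
    "BANDS",
    "PairedTcbTsb",
    "SrbvRecord",
    "BandSummary",
    "compute_srbv",
    "assign_band",
    "summarise_bands",
    "average_across_sites",
    "round_half_up",
]

Stage = Literal["pre_treatment", "mid_treatment", "end_treatment"]
Band = Literal["lt9", "b9_115", "b116_15", "gt15"]

#: Severity bands on the composite reading, mg/dL.  Readings are recorded
#: to 0.1 mg/dL in the field, so the closed/open split at 11.5 is lossless
#: there; for continuous simulated values the convention is
#: [0,9), [9,11.5], (11.5,15], (15,inf).
BANDS: tuple[Band, ...] = ("lt9", "b9_115", "b116_15", "gt15")

STAGES: tuple[Stage, ...] = ("pre_treatment", "mid_treatment", "end_treatment")


@dataclass(frozen=True)
class PairedTcbTsb:
    neonate_id: str
    site_id: str
    stage: Stage
    tbl: float  # calibrated composite reading, mg/dL
    tsb: float  # laboratory serum value, mg/dL

    def __post_init__(self) -> None:
        if self.tbl <= 0 or self.tsb <= 0:
            raise ValueError("tbl and tsb must be > 0")


@dataclass(frozen=True)
class SrbvRecord:
    neonate_id: str
    site_id: str
    stage: Stage
    tbl: float
    tsb: float
    srbv: float
    srbv_fraction: float | None  # None when the residual is negative
    band: Band
    negative_flag: bool


@dataclass(frozen=True)
class BandSummary:
    site_id: str  # a centre id, or "Average" for the across-site row
    stage: Stage
    band: Band
    mean_fraction_pct: float | None  # None encodes an NA cell
    sd_fraction: float | None
    n: int


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (display convention)."""
    return int(math.floor(x + 0.5))


def assign_band(tbl: float) -> Band:
    if tbl <= 0:
        raise ValueError("tbl must be > 0")
    if tbl < 9.0:
        return "lt9"
    if tbl <= 11.5:
        return "b9_115"
    if tbl <= 15.0:
        return "b116_15"
    return "gt15"


def compute_srbv(pair: PairedTcbTsb) -> SrbvRecord:
    """Derive the skin residual and its fraction for one paired reading."""
    srbv = pair.tbl - pair.tsb
    negative = srbv < 0
    fraction = None if negative else srbv / pair.tbl
    return SrbvRecord(
        neonate_id=pair.neonate_id,
        site_id=pair.site_id,
        stage=pair.stage,
        tbl=pair.tbl,
        tsb=pair.tsb,
        srbv=srbv,
        srbv_fraction=fraction,
        band=assign_band(pair.tbl),
        negative_flag=negative,
    )


def summarise_bands(records: Iterable[SrbvRecord]) -> list[BandSummary]:
    """Per (site, stage, band) mean and SD of the non-negative fractions.

    Cells with no eligible records are emitted as NA (mean/sd None, n 0).
    Every (stage, band) combination observed for a site's stage grid is
    emitted so NA cells are explicit, as in the published summaries.
    Percentages keep full precision here; display rounding is half-up.
    """
    recs = list(records)
    if not recs:
        return []
    sites = sorted({r.site_id for r in recs})
    out: list[BandSummary] = []
    for site in sites:
        for stage in STAGES:
            stage_recs = [r for r in recs if r.site_id == site and r.stage == stage]
            if not stage_recs:
                continue  # stage never sampled at this site
            for band in BANDS:
                cell = [
                    r.srbv_fraction
                    for r in stage_recs
                    if r.band == band and not r.negative_flag
                ]
                if not cell:
                    out.append(BandSummary(site, stage, band, None, None, 0))
                    continue
                arr = np.array(cell)
                sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
                out.append(
                    BandSummary(
                        site_id=site,
                        stage=stage,
                        band=band,
                        mean_fraction_pct=float(arr.mean() * 100.0),
                        sd_fraction=sd,
                        n=len(arr),
                    )
                )
    return out


def average_across_sites(summaries: Sequence[BandSummary]) -> list[BandSummary]:
    """Unweighted across-site mean of per-site mean percentages.

    Each output cell averages the non-NA site cells for that (stage, band);
    an all-NA cell stays NA.  Unweighted averaging of site means (rather
    than pooling by n) is what reproduces the published across-site row.
    """
    out: list[BandSummary] = []
    stages = []
    for s in summaries:
        if s.stage not in stages:
            stages.append(s.stage)
    for stage in stages:
        for band in BANDS:
            cells = [
                s
                for s in summaries
                if s.stage == stage and s.band == band and s.site_id != "Average"
            ]
            if not cells:
                continue
            vals = [s.mean_fraction_pct for s in cells if s.mean_fraction_pct is not None]
            if not vals:
                out.append(BandSummary("Average", stage, band, None, None, 0))
                continue
            out.append(
                BandSummary(
                    site_id="Average",
                    stage=stage,
                    band=band,
                    mean_fraction_pct=float(np.mean(vals)),
                    sd_fraction=None,
                    n=sum(s.n for s in cells),
                )
            )
    return out
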