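"""Published site-level summary statistics of the six-hospital field cohort.

These are the printed per-centre summaries from the multicentre
observational study of transcutaneous bilirubin behaviour during
phototherapy in southeastern Nigeria.  The raw per-patient records were
never deposited, so these aggregates serve two roles here: they are the
reference against which the package's summary operations are checked, and
they parameterise the default synthetic cohort so simulated sites mirror
the field structure (counts, ages, baseline levels and ranges).

Percent SRBV cells are per-site means of the skin-residual fraction of the
composite reading, stratified by severity band and treatment stage; ``None``
marks cells where no paired laboratory data were captured.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SiteCharacteristics",
    "SITE_CHARACTERISTICS",
    "SRBV_FRACTION_CELLS",
    "OVERALL_RVP_IDENTIFIED_PCT",
]


@dataclass(frozen=True)
class SiteCharacteristics:
    """One centre's published cohort summary row."""

    site_id: str
    n_patients: int
    age_days_mean: float
    age_days_sd: float
    pretreatment_tbl_mean: float
    tbl_range: tuple[float, float]
    decline_rate: float  # mg/dL/h
    rvp_observed_pct: float


SITE_CHARACTERISTICS: tuple[SiteCharacteristics, ...] = (
    SiteCharacteristics("BSH", 23, 5.7, 2.4, 14.03, (10.0, 28.0), 0.27, 91.0),
    SiteCharacteristics("SPH", 23, 3.8, 1.6, 12.37, (8.9, 18.4), 0.52, 100.0),
    SiteCharacteristics("MJH", 10, 5.7, 3.3, 12.29, (10.4, 14.9), 0.23, 100.0),
    SiteCharacteristics("IHH", 20, 2.7, 2.1, 8.97, (6.8, 14.3), 0.21, 71.0),
    SiteCharacteristics("MCH", 13, 3.8, 1.8, 16.33, (10.7, 23.5), 0.18, 92.0),
    SiteCharacteristics("IHMH", 13, 3.7, 2.2, 15.22, (8.3, 30.4), 0.18, 100.0),
)

#: Share of patients with adequate serial data in whom the recovery value
#: flip was clearly identifiable, pooled over all centres.
OVERALL_RVP_IDENTIFIED_PCT = 92.0

#: Per-site mean %SRBV of the composite reading by (site, stage, band).
#: stage in {"pre_treatment", "end_treatment"};
#: band in {"lt9", "b9_115", "b116_15"}; values are (mean_pct, sd) or None.
SRBV_FRACTION_CELLS: dict[str, dict[str, dict[str, tuple[float, float] | None]]] = {
    "BSH": {
        "pre_treatment": {"lt9": None, "b9_115": (30.0, 0.02), "b116_15": (9.0, 0.04)},
        "end_treatment": {"lt9": (17.0, 0.09), "b9_115": (27.0, 0.07), "b116_15": (24.0, 0.03)},
    },
    "MCH": {
        "pre_treatment": {"lt9": None, "b9_115": (11.0, 0.02), "b116_15": (12.0, 0.05)},
        "end_treatment": {"lt9": None, "b9_115": None, "b116_15": None},
    },
    "IHMH": {
        "pre_treatment": {"lt9": None, "b9_115": None, "b116_15": None},
        "end_treatment": {"lt9": (21.0, 0.05), "b9_115": (11.0, 0.04), "b116_15": (28.0, 0.03)},
    },
}
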