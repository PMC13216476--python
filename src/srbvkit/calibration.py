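"""Centre-specific device calibration against laboratory serum bilirubin.

Each centre derives a single multiplicative coefficient from paired
(raw device reading, laboratory TSB) values collected in non-jaundiced
neonates (TSB < 3 mg/dL), where the skin residual component is negligible
and the device should read serum directly.  The default fit is least
squares through the origin — a lone "coefficient" implies one number, and
an intercept would be a second; a ratio-of-means alternative is kept for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationPair",
    "CalibrationModel",
    "fit_calibration",
    "apply_calibration",
    "fit_all_sites",
    "TSB_ELIGIBILITY_LIMIT",
]

log = logging.getLogger(__name__)

#: Pairs are eligible for fitting only below this laboratory value (mg/dL),
#: strictly — the regime where bilirubin remains intravascular.
TSB_ELIGIBILITY_LIMIT = 3.0

FitMethod = Literal["origin", "ratio"]


@dataclass(frozen=True)
class CalibrationPair:
    tbl_raw: float
    tsb: float

    def __post_init__(self) -> None:
        if self.tbl_raw <= 0 or self.tsb <= 0:
            raise ValueError("calibration readings must be > 0")


@dataclass(frozen=True)
class CalibrationModel:
    site_id: str
    coefficient: float
    n_pairs: int
    fit_residual_cv: float
    method: FitMethod = "origin"

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")


def fit_calibration(
    pairs: Iterable[CalibrationPair | tuple[float, float]],
    site_id: str,
    method: FitMethod = "origin",
) -> CalibrationModel:
    """Fit the centre's multiplicative coefficient from eligible pairs.

    ``origin`` minimises sum((c*tbl_raw - tsb)^2), giving the closed form
    c = sum(tbl*tsb)/sum(tbl^2); ``ratio`` uses mean(tsb)/mean(tbl_raw).
    Pairs at or above the 3 mg/dL eligibility limit are excluded (their
    count is logged); fewer than two eligible pairs is an error.
    """
    norm = [p if isinstance(p, CalibrationPair) else CalibrationPair(*p) for p in pairs]
    eligible = [p for p in norm if p.tsb < TSB_ELIGIBILITY_LIMIT]
    excluded = len(norm) - len(eligible)
    if excluded:
        log.info("site %s: excluded %d pairs with TSB >= %.1f mg/dL",
                 site_id, excluded, TSB_ELIGIBILITY_LIMIT)
    if len(eligible) < 2:
        raise ValueError(
            f"site {site_id}: need >= 2 eligible pairs (TSB < "
            f"{TSB_ELIGIBILITY_LIMIT} mg/dL), got {len(eligible)}"
        )
    tbl = np.array([p.tbl_raw for p in eligible])
    tsb = np.array([p.tsb for p in eligible])
    if method == "origin":
        coeff = float(np.dot(tbl, tsb) / np.dot(tbl, tbl))
    elif method == "ratio":
        coeff = float(tsb.mean() / tbl.mean())
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = coeff * tbl - tsb
    residual_cv = float(np.sqrt(np.mean(resid**2)) / tsb.mean())
    return CalibrationModel(
        site_id=site_id,
        coefficient=coeff,
        n_pairs=len(eligible),
        fit_residual_cv=residual_cv,
        method=method,
    )


def apply_calibration(model: CalibrationModel, tbl_raw: float) -> float:
    """Deterministically rescale one raw reading to the laboratory scale."""
    if tbl_raw <= 0:
        raise ValueError("tbl_raw must be > 0")
    return model.coefficient * tbl_raw


def fit_all_sites(
    pairs_table: pd.DataFrame, method: FitMethod = "origin"
) -> pd.DataFrame:
    """Fit one model per site from a (site_id, tbl_raw, tsb) table.

    Calibration is never pooled across centres.
    """
    required = {"site_id", "tbl_raw", "tsb"}
    missing = required - set(pairs_table.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    rows = []
    for site_id, grp in pairs_table.groupby("site_id", sort=True):
        model = fit_calibration(
            list(zip(grp["tbl_raw"], grp["tsb"])), str(site_id), method=method
        )
        rows.append(
            {
                "site_id": model.site_id,
                "coefficient": model.coefficient,
                "n_pairs": model.n_pairs,
                "fit_residual_cv": model.fit_residual_cv,
                "method": model.method,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "coefficient", "n_pairs", "fit_residual_cv", "method"])
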