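"""CSV and configuration I/O for the monitoring pipeline.

All tabular interchange is UTF-8 CSV with a header row and '.' decimal
separator; the long measurement format (one row per reading) is shared by
the simulator and field data entry so irregular sampling and missing
returns need no special casing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "MEASUREMENT_COLUMNS",
    "ValidationIssue",
    "read_measurements",
    "write_csv",
    "load_config_file",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["neonate_id", "site_id", "time_h", "phase", "kind", "value_mg_dl"]
VALID_PHASES = {"out", "return", "pre", "mid", "end"}
VALID_KINDS = {"TBL_raw", "TBL", "TSB"}


@dataclass(frozen=True)
class ValidationIssue:
    line: int  # 1-based line number in the file (header is line 1)
    message: str


def read_measurements(path: str | Path) -> tuple[pd.DataFrame, list[ValidationIssue]]:
    """Read and validate a long-format measurement CSV.

    Returns the accepted rows (typed) and the list of rejected rows with
    their file line numbers.  Input row count always equals accepted plus
    rejected.  CRLF and LF files parse identically.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")

    issues: list[ValidationIssue] = []
    accepted = []
    seen: set[tuple[str, float, str]] = set()
    for idx, row in raw.iterrows():
        line = int(idx) + 2  # header occupies line 1
        try:
            time_h = float(row["time_h"])
            value = float(row["value_mg_dl"])
        except ValueError:
            issues.append(ValidationIssue(line, "non-numeric time_h or value_mg_dl"))
            continue
        if value <= 0:
            issues.append(ValidationIssue(line, f"non-positive value_mg_dl: {value}"))
            continue
        if time_h < 0:
            issues.append(ValidationIssue(line, f"negative time_h: {time_h}"))
            continue
        if row["phase"] not in VALID_PHASES:
            issues.append(ValidationIssue(line, f"unknown phase: {row['phase']!r}"))
            continue
        if row["kind"] not in VALID_KINDS:
            issues.append(ValidationIssue(line, f"unknown kind: {row['kind']!r}"))
            continue
        key = (row["neonate_id"], time_h, row["kind"])
        if key in seen:
            issues.append(ValidationIssue(line, f"duplicate (neonate_id, time_h, kind): {key}"))
            continue
        seen.add(key)
        accepted.append(
            {
                "neonate_id": row["neonate_id"],
                "site_id": row["site_id"],
                "time_h": time_h,
                "phase": row["phase"],
                "kind": row["kind"],
                "value_mg_dl": value,
            }
        )
    for issue in issues:
        log.warning("%s line %d: %s", path, issue.line, issue.message)
    log.info(
        "%s: %d rows accepted, %d rejected", path, len(accepted), len(issues)
    )
    return pd.DataFrame(accepted, columns=MEASUREMENT_COLUMNS), issues


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a table with stable column order and no index column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline configuration mapping."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
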