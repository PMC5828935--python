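"""Tidy long-format dataset reader/writer with unit normalization.

The dataset dialect is a NONMEM-style long CSV with one record per row:

    subject_id, group_id, time_h, record_type, value, unit, drug,
    interval_start_h, interval_end_h

``record_type`` is one of ``dose`` (mg), ``drug_conc`` (ng/mL),
``serum_ua`` (mg/L, or mg/dL which is converted on read) and ``urine_ua``
(mg, with both interval bounds present).  Reading validates rows and
normalizes values to internal units; rejected rows are logged with their
line numbers rather than aborting the whole read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("uadyn.io")

__all__ = ["TidyDataset", "read_dataset", "write_dataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = [
    "subject_id",
    "group_id",
    "time_h",
    "record_type",
    "value",
    "unit",
    "drug",
    "interval_start_h",
    "interval_end_h",
]

# record type -> {accepted unit: factor to internal unit}
_UNIT_RULES: dict[str, dict[str, float]] = {
    "serum_ua": {"mg/L": 1.0, "mg/dL": 10.0},
    "urine_ua": {"mg": 1.0},
    "drug_conc": {"ng/mL": 1.0, "mg/L": 1000.0, "ug/mL": 1000.0},
    "dose": {"mg": 1.0},
}
_INTERNAL_UNITS = {
    "serum_ua": "mg/L",
    "urine_ua": "mg",
    "drug_conc": "ng/mL",
    "dose": "mg",
}


@dataclass
class TidyDataset:
    """Validated, unit-normalized observation table plus a rejection log."""

    frame: pd.DataFrame
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def records(self, record_type: str) -> pd.DataFrame:
        return self.frame[self.frame["record_type"] == record_type]


def read_dataset(path) -> TidyDataset:
    """Read and validate a tidy CSV dataset; normalize to internal units.

    Missing required columns raise immediately; invalid rows (unknown
    record type, unsupported unit, negative time, non-numeric value, urine
    rows without both interval bounds) are dropped, each logged with its
    1-based file line number.
    """
    raw = pd.read_csv(
        path,
        dtype={"subject_id": str, "group_id": str, "drug": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"dataset {path} is missing required columns: {missing}")

    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(raw), dtype=bool)
    values = pd.to_numeric(raw["value"], errors="coerce").astype(float)
    times = pd.to_numeric(raw["time_h"], errors="coerce").astype(float)

    for i in range(len(raw)):
        line = i + 2  # header is line 1
        rtype = raw.at[i, "record_type"]
        if rtype not in _UNIT_RULES:
            rejected.append((line, f"unknown record_type {rtype!r}"))
            keep[i] = False
            continue
        unit = raw.at[i, "unit"]
        if unit not in _UNIT_RULES[rtype]:
            rejected.append((line, f"unsupported unit {unit!r} for {rtype}"))
            keep[i] = False
            continue
        if not np.isfinite(values.iloc[i]):
            rejected.append((line, "non-numeric value"))
            keep[i] = False
            continue
        if not np.isfinite(times.iloc[i]) or times.iloc[i] < 0:
            rejected.append((line, f"invalid time {raw.at[i, 'time_h']}"))
            keep[i] = False
            continue
        if rtype == "urine_ua":
            start = pd.to_numeric(raw.at[i, "interval_start_h"], errors="coerce")
            end = pd.to_numeric(raw.at[i, "interval_end_h"], errors="coerce")
            if not (np.isfinite(start) and np.isfinite(end) and start < end):
                rejected.append((line, "urine row without valid interval bounds"))
                keep[i] = False
                continue

    frame = raw.loc[keep].copy()
    frame["value"] = values.loc[keep]
    frame["time_h"] = times.loc[keep]
    factors = frame.apply(
        lambda r: _UNIT_RULES[r["record_type"]][r["unit"]], axis=1
    ) if len(frame) else pd.Series(dtype=float)
    frame["value"] = frame["value"] * factors
    frame["unit"] = frame["record_type"].map(_INTERNAL_UNITS)
    frame = frame.reset_index(drop=True)

    logger.info(
        "read %d rows from %s (%d rejected)", len(frame), path, len(rejected)
    )
    for line, reason in rejected:
        logger.warning("rejected line %d: %s", line, reason)
    return TidyDataset(frame=frame, rejected=rejected)


def write_dataset(frame: pd.DataFrame, path) -> None:
    """Write a tidy dataset CSV (columns ordered, stable float formatting)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset frame is missing columns: {missing}")
    frame[REQUIRED_COLUMNS].to_csv(path, index=False, float_format="%.10g")
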