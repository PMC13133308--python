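"""Typed data model and delimited-file I/O for ICU cohort extracts.

The pipeline consumes five flat CSV tables (UTF-8, comma-delimited, free text
quoted), mirroring what a SQL export from a critical-care database looks like
after de-identification:

``stays.csv``
    one row per ICU stay: ``stay_id, subject_id, icu_in, icu_out, death_time``.
``events.csv``
    timestamped physiologic / ventilator / blood-gas measurements:
    ``stay_id, time, kind, value`` with ``kind`` one of :class:`ObsKind`.
``reports.csv``
    radiology report text: ``stay_id, time, text``.
``icd.csv``
    discharge diagnosis codes: ``stay_id, code, version`` (9 or 10).
``labels.csv``
    expert adjudication: ``stay_id, label`` with a three-class label
    (ARDS / POSSIBLE / NON_ARDS_AHRF).

Timestamps are ISO-8601 strings at minute resolution in files and
``datetime64[ns]`` in memory; all interval arithmetic downstream is done in
hours as floats.

Unit conventions enforced here:

* FiO2 values in ``(1, 100]`` are interpreted as percentages and divided by
  100; values in ``(0, 1]`` are already fractions; values above 100 (or not
  positive) are invalid. Normalisation is idempotent.
* ICD codes are canonicalised to dot-free uppercase (``J80``, ``51882``).
* PaO2 is assumed to be mm Hg. Sites recording kPa must pre-convert
  (multiply by 7.50062); no automatic unit guessing is performed.

Rows violating row-level invariants are *rejected* with per-row diagnostics
(kept on :attr:`CohortBundle.rejected`); structural problems (missing columns,
events referencing unknown stays) raise :class:`SchemaError` /
:class:`ReferentialError`.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIME_FORMAT = "%Y-%m-%dT%H:%M"

STAYS_COLUMNS = ["stay_id", "subject_id", "icu_in", "icu_out", "death_time"]
EVENTS_COLUMNS = ["stay_id", "time", "kind", "value"]
REPORTS_COLUMNS = ["stay_id", "time", "text"]
ICD_COLUMNS = ["stay_id", "code", "version"]
LABELS_COLUMNS = ["stay_id", "label"]


class ObsKind(str, enum.Enum):
    """Kinds of timestamped observations the screen consumes."""

    PAO2 = "pao2_mmHg"
    FIO2 = "fio2_fraction"
    PEEP = "peep_cmH2O"
    VENT = "vent_flag"


class Label(str, enum.Enum):
    """Three-class expert adjudication label."""

    ARDS = "ARDS"
    POSSIBLE = "POSSIBLE"
    NON_ARDS_AHRF = "NON_ARDS_AHRF"


class SchemaError(ValueError):
    """A file does not conform to its documented column schema."""


class ReferentialError(ValueError):
    """A table references stay_ids absent from the stays table."""


class InvalidMeasurementError(ValueError):
    """A physiologic value is outside its admissible range (e.g. FiO2 = 0)."""


@dataclass
class CohortBundle:
    """In-memory cohort: five tables plus row-level rejection diagnostics."""

    stays: pd.DataFrame
    events: pd.DataFrame
    reports: pd.DataFrame
    icd: pd.DataFrame
    labels: pd.DataFrame
    rejected: dict[str, pd.DataFrame] = field(default_factory=dict)

    def n_rejected(self) -> int:
        return sum(len(df) for df in self.rejected.values())


def normalize_fio2(values: np.ndarray | pd.Series) -> np.ndarray:
    """Normalise FiO2 to a fraction in (0, 1].

    Values in ``(1, 100]`` are treated as percentages and divided by 100.
    Values outside ``(0, 100]`` become NaN (invalid). Idempotent.
    """
    v = np.asarray(values, dtype=float).copy()
    invalid = ~np.isfinite(v) | (v <= 0) | (v > 100)
    percent = (v > 1) & ~invalid
    v[percent] = v[percent] / 100.0
    v[invalid] = np.nan
    return v


def canonical_icd(code: str) -> str:
    """Canonical ICD form: uppercase, dots and surrounding whitespace removed."""
    return str(code).strip().upper().replace(".", "")


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _parse_times(series: pd.Series) -> pd.Series:
    out = pd.to_datetime(series, errors="coerce", format="ISO8601")
    return out.dt.floor("min")


def _reject(df: pd.DataFrame, bad: pd.Series, reason: str, sink: list[pd.DataFrame]) -> pd.DataFrame:
    """Split off rows flagged by ``bad``, annotating them with ``reason``."""
    bad = bad.fillna(False).astype(bool)
    if bad.any():
        rej = df.loc[bad].copy()
        rej["reason"] = reason
        sink.append(rej)
    return df.loc[~bad]


def _validate_stays(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    _require_columns(df, STAYS_COLUMNS, "stays")
    df = df.copy()
    df["stay_id"] = df["stay_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("icu_in", "icu_out", "death_time"):
        df[col] = _parse_times(df[col])
    sink: list[pd.DataFrame] = []
    df = _reject(df, df["icu_in"].isna() | df["icu_out"].isna(), "unparseable icu_in/icu_out", sink)
    df = _reject(df, df["icu_in"] >= df["icu_out"], "icu_in >= icu_out", sink)
    df = _reject(df, df["death_time"].notna() & (df["death_time"] < df["icu_in"]),
                 "death_time before icu_in", sink)
    df = _reject(df, df["stay_id"].duplicated(keep=False), "duplicate stay_id", sink)
    rejected = pd.concat(sink) if sink else pd.DataFrame(columns=list(df.columns) + ["reason"])
    return df.reset_index(drop=True), rejected


def _validate_events(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    _require_columns(df, EVENTS_COLUMNS, "events")
    df = df.copy()
    df["stay_id"] = df["stay_id"].astype(str)
    df["time"] = _parse_times(df["time"])
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    sink: list[pd.DataFrame] = []
    kinds = {k.value for k in ObsKind}
    df = _reject(df, df["time"].isna(), "unparseable time", sink)
    df = _reject(df, ~df["kind"].isin(kinds), "unknown kind", sink)
    df = _reject(df, df["value"].isna(), "non-numeric value", sink)

    is_pao2 = df["kind"] == ObsKind.PAO2.value
    df = _reject(df, is_pao2 & (df["value"] <= 0), "pao2 must be > 0", sink)
    is_fio2 = df["kind"] == ObsKind.FIO2.value
    norm = normalize_fio2(df.loc[is_fio2, "value"])
    df.loc[is_fio2, "value"] = norm
    df = _reject(df, (df["kind"] == ObsKind.FIO2.value) & df["value"].isna(),
                 "fio2 outside (0, 100]", sink)
    is_peep = df["kind"] == ObsKind.PEEP.value
    df = _reject(df, is_peep & (df["value"] < 0), "peep must be >= 0", sink)
    is_vent = df["kind"] == ObsKind.VENT.value
    df = _reject(df, is_vent & ~df["value"].isin([0.0, 1.0]), "vent_flag must be 0 or 1", sink)

    rejected = pd.concat(sink) if sink else pd.DataFrame(columns=list(df.columns) + ["reason"])
    df = df.sort_values(["stay_id", "time"], kind="stable").reset_index(drop=True)
    return df, rejected


def _check_refs(df: pd.DataFrame, known: set[str], name: str) -> None:
    unknown = sorted(set(df["stay_id"]) - known)
    if unknown:
        raise ReferentialError(f"{name}: unresolvable stay_id(s): {unknown}")


def read_cohort(directory: str | Path, *, require_labels: bool = False) -> CohortBundle:
    """Read a cohort from a directory of CSV files.

    ``stays.csv`` and ``events.csv`` are required; ``reports.csv``,
    ``icd.csv`` and ``labels.csv`` are optional (empty tables are substituted
    when absent, unless ``require_labels``).

    Raises
    ------
    SchemaError
        when a required file or column is missing.
    ReferentialError
        when any table references a stay_id not present in stays.
    """
    directory = Path(directory)
    rejected: dict[str, pd.DataFrame] = {}

    def _load(name: str, required: bool, columns: list[str]) -> pd.DataFrame:
        path = directory / f"{name}.csv"
        if not path.exists():
            if required:
                raise SchemaError(f"required file not found: {path}")
            return pd.DataFrame(columns=columns)
        return pd.read_csv(path, dtype=str, keep_default_na=True)

    stays_raw = _load("stays", True, STAYS_COLUMNS)
    events_raw = _load("events", True, EVENTS_COLUMNS)
    stays, rejected["stays"] = _validate_stays(stays_raw)
    events, rejected["events"] = _validate_events(events_raw)

    reports = _load("reports", False, REPORTS_COLUMNS)
    _require_columns(reports, REPORTS_COLUMNS, "reports")
    reports = reports.copy()
    if len(reports):
        reports["stay_id"] = reports["stay_id"].astype(str)
        reports["time"] = _parse_times(reports["time"])
        sink: list[pd.DataFrame] = []
        reports = _reject(reports, reports["time"].isna(), "unparseable time", sink)
        reports = _reject(reports, reports["text"].isna() | (reports["text"].astype(str).str.strip() == ""),
                          "empty text", sink)
        rejected["reports"] = pd.concat(sink) if sink else pd.DataFrame(columns=list(reports.columns) + ["reason"])
        reports = reports.sort_values(["stay_id", "time"], kind="stable").reset_index(drop=True)

    icd = _load("icd", False, ICD_COLUMNS)
    _require_columns(icd, ICD_COLUMNS, "icd")
    icd = icd.copy()
    if len(icd):
        icd["stay_id"] = icd["stay_id"].astype(str)
        icd["code"] = icd["code"].map(canonical_icd)
        icd["version"] = pd.to_numeric(icd["version"], errors="coerce").astype("Int64")
        sink = []
        icd = _reject(icd, icd["code"] == "", "empty code", sink)
        icd = _reject(icd, ~icd["version"].isin([9, 10]), "version must be 9 or 10", sink)
        rejected["icd"] = pd.concat(sink) if sink else pd.DataFrame(columns=list(icd.columns) + ["reason"])
        icd = icd.reset_index(drop=True)

    labels_path = directory / "labels.csv"
    if require_labels and not labels_path.exists():
        raise SchemaError(f"labels required: {labels_path} not found")
    labels = _load("labels", False, LABELS_COLUMNS)
    _require_columns(labels, LABELS_COLUMNS, "labels")
    labels = labels.copy()
    if len(labels):
        labels["stay_id"] = labels["stay_id"].astype(str)
        sink = []
        labels = _reject(labels, ~labels["label"].isin({l.value for l in Label}), "unknown label", sink)
        dup = labels["stay_id"].duplicated(keep=False)
        if dup.any():
            raise SchemaError(
                f"labels: more than one label for stay_id(s) {sorted(labels.loc[dup, 'stay_id'].unique())}")
        rejected["labels"] = pd.concat(sink) if sink else pd.DataFrame(columns=list(labels.columns) + ["reason"])
        labels = labels.reset_index(drop=True)

    known = set(stays["stay_id"])
    for name, df in (("events", events), ("reports", reports), ("icd", icd), ("labels", labels)):
        if len(df):
            _check_refs(df, known, name)

    bundle = CohortBundle(stays=stays, events=events, reports=reports, icd=icd,
                          labels=labels, rejected=rejected)
    n_rej = bundle.n_rejected()
    logger.info("read_cohort: %d stays, %d events, %d reports, %d icd, %d labels (%d rows rejected)",
                len(stays), len(events), len(reports), len(icd), len(labels), n_rej)
    if n_rej:
        for name, df in rejected.items():
            for reason, cnt in df.get("reason", pd.Series(dtype=str)).value_counts().items():
                logger.warning("read_cohort: %s: rejected %d row(s): %s", name, cnt, reason)
    return bundle


def _fmt_times(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        if c in out.columns:
            out[c] = pd.to_datetime(out[c]).dt.strftime(TIME_FORMAT)
    return out


def write_cohort(bundle: CohortBundle, directory: str | Path) -> None:
    """Write a bundle back to CSV files; ``read_cohort`` round-trips it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _fmt_times(bundle.stays, ["icu_in", "icu_out", "death_time"]).to_csv(directory / "stays.csv", index=False)
    _fmt_times(bundle.events, ["time"]).to_csv(directory / "events.csv", index=False)
    if len(bundle.reports):
        _fmt_times(bundle.reports, ["time"]).to_csv(directory / "reports.csv", index=False)
    if len(bundle.icd):
        bundle.icd.to_csv(directory / "icd.csv", index=False)
    if len(bundle.labels):
        bundle.labels.to_csv(directory / "labels.csv", index=False)


def write_table(df: pd.DataFrame, path: str | Path, time_cols: tuple[str, ...] = ("onset",)) -> None:
    """Write a results table (e.g. screen_results.csv) with ISO-minute timestamps."""
    _fmt_times(df, list(time_cols)).to_csv(path, index=False)


def read_table(path: str | Path, time_cols: tuple[str, ...] = ("onset",)) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stay_id": str, "subject_id": str})
    for c in time_cols:
        if c in df.columns:
            df[c] = _parse_times(df[c])
    return df


def write_metrics(metrics: Mapping, path: str | Path) -> None:
    """Serialise a metrics mapping to JSON (None for undefined metrics)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, allow_nan=False, default=float)
        fh.write("\n")


def read_metrics(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
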