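"""Shared fixtures: tiny hand-built cohorts and one large seeded cohort.

The large cohort (20,000 subjects at the within-screen calibration) is
expensive, so it is generated once per session and shared by the
parameter-recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ardscreen.ehr_model import CohortBundle
from ardscreen.enrich import default_rulesets, enrich_cohort
from ardscreen.screen import in_window, screen_cohort
from ardscreen.synth import default_calibration, simulate_cohort

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")

BASE = pd.Timestamp("2024-01-01 00:00")


def T(hours: float) -> pd.Timestamp:
    """Timestamp ``hours`` after the fixture epoch."""
    return BASE + pd.Timedelta(hours=hours)


def make_stays(rows) -> pd.DataFrame:
    """rows: (stay_id, subject_id, in_h, out_h, death_h_or_None)."""
    df = pd.DataFrame(
        [{"stay_id": s, "subject_id": p, "icu_in": T(a), "icu_out": T(b),
          "death_time": T(d) if d is not None else pd.NaT}
         for s, p, a, b, d in rows],
        columns=["stay_id", "subject_id", "icu_in", "icu_out", "death_time"])
    if len(df) == 0:
        for c in ("icu_in", "icu_out", "death_time"):
            df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def make_events(rows) -> pd.DataFrame:
    """rows: (stay_id, t_h, kind, value)."""
    df = pd.DataFrame([{"stay_id": s, "time": T(t), "kind": k, "value": float(v)}
                       for s, t, k, v in rows],
                      columns=["stay_id", "time", "kind", "value"])
    if len(df) == 0:
        df["time"] = pd.Series(dtype="datetime64[ns]")
    return df.sort_values(["stay_id", "time"], kind="stable").reset_index(drop=True)


def make_bundle(stays_rows, events_rows, reports_rows=(), icd_rows=(),
                labels_rows=()) -> CohortBundle:
    reports = pd.DataFrame([{"stay_id": s, "time": T(t), "text": txt}
                            for s, t, txt in reports_rows],
                           columns=["stay_id", "time", "text"])
    if len(reports):
        reports["time"] = pd.to_datetime(reports["time"])
    icd = pd.DataFrame([{"stay_id": s, "code": c, "version": v} for s, c, v in icd_rows],
                       columns=["stay_id", "code", "version"])
    labels = pd.DataFrame([{"stay_id": s, "label": l} for s, l in labels_rows],
                          columns=["stay_id", "label"])
    return CohortBundle(stays=make_stays(stays_rows), events=make_events(events_rows),
                        reports=reports, icd=icd, labels=labels)


def hypoxic_stay_events(stay_id: str, n_days: int, pf: float = 150.0,
                        peep: float = 8.0, per_day: int = 3):
    """Events giving a stay ``n_days`` qualifying 24-h windows."""
    rows = []
    for d in range(n_days):
        for j in range(per_day):
            t = d * 24 + 2 + j * 8
            rows.append((stay_id, t, "pao2_mmHg", pf * 0.5))
            rows.append((stay_id, t, "fio2_fraction", 0.5))
            rows.append((stay_id, t + 0.5, "peep_cmH2O", peep))
    return rows


@pytest.fixture(scope="session")
def big_cohort():
    """20,000-subject within-screen cohort run through the full pipeline."""
    cfg = default_calibration(n_subjects=20000, seed=20260924)
    bundle = simulate_cohort(cfg)
    results = screen_cohort(bundle)
    h72 = results[in_window(results, "72")]
    flags = enrich_cohort(bundle, h72, default_rulesets()["T3"])
    labels = bundle.labels[bundle.labels["stay_id"].isin(set(h72["stay_id"]))]
    return {"config": cfg, "bundle": bundle, "results": results, "h72": h72,
            "flags": flags, "labels": labels}
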