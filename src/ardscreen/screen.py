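"""Persistence episode detection and cohort classification.

A stay *qualifies* in a given 24-h window when its mean P/F contemporaneous
with PEEP ≥ 5 cm H2O is below 300 mm Hg (see :mod:`ardscreen.harmonize`).
This module finds, per stay, the first unbroken run of qualifying windows
(the screening *episode*) and grades persistence:

``H72``
    ≥ 3 consecutive qualifying windows, or ≥ 2 with death on the third day
    after onset (death in ``[onset+48 h, onset+72 h)``).
``H48``
    ≥ 2 consecutive qualifying windows.
``H24``
    ≥ 1 qualifying window.
``ANYTIME_ONLY``
    no qualifying window, but at least one single paired measurement with
    P/F < 300 and PEEP ≥ 5 at some point during the stay.

The four screening cohorts nest: H72 ⊆ H48 ⊆ H24 ⊆ ANYTIME (as subject
sets). Persistence is counted over *complete* 24-h windows only — a trailing
partial window is reported but cannot extend a run, so a stay discharged
alive at 50 h grades H48, not H72; censoring by death is handled explicitly
by the death-on-day-3 rule. A broken run (qualify / not / qualify) restarts
the count: "sustained" means consecutive.

For subjects with multiple ICU stays, the first stay (by admission time)
meeting any screening criterion is retained.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ehr_model import CohortBundle, ObsKind
from .harmonize import (DEFAULT_PAIRING_TOLERANCE_H, PEEP_THRESHOLD_CMH2O,
                        PF_THRESHOLD_MMHG, WINDOW_H, harmonize_cohort)

logger = logging.getLogger(__name__)


class PersistenceClass(str, enum.Enum):
    ANYTIME_ONLY = "ANYTIME_ONLY"
    H24 = "H24"
    H48 = "H48"
    H72 = "H72"


#: nesting order, weakest to strictest
_CLASS_ORDER = [PersistenceClass.ANYTIME_ONLY, PersistenceClass.H24,
                PersistenceClass.H48, PersistenceClass.H72]


class Stratum(str, enum.Enum):
    """Hypoxaemia-duration stratum for the missed-case analysis."""

    H0_24 = "h0_24"
    H24_48 = "h24_48"
    H48_72PLUS = "h48_72plus"


@dataclass(frozen=True)
class Episode:
    """First run of consecutive qualifying complete 24-h windows."""

    stay_id: str
    onset: pd.Timestamp          # start of the first qualifying window
    onset_index: int
    n_consecutive: int


SCREEN_COLUMNS = ["subject_id", "stay_id", "onset", "n_consecutive", "anytime",
                  "persistence_class", "stratum", "excluded_early_death",
                  "death_within_48_72h", "vent_at_onset", "vent_after_onset"]


def find_first_episode(
    windows: pd.DataFrame,
    pfpoints: pd.DataFrame,
) -> tuple[Optional[Episode], bool, Optional[pd.Timestamp]]:
    """Locate the first persistence episode of one stay.

    Parameters
    ----------
    windows
        The stay's day windows, ordered by index.
    pfpoints
        The stay's paired P/F points (for the any-measurement screen).

    Returns
    -------
    (episode, anytime, first_hit_time)
        ``episode`` is None when no complete window qualifies. ``anytime`` is
        True when any single paired measurement ever met P/F < 300 with
        PEEP ≥ 5; ``first_hit_time`` is the time of the earliest such
        measurement (None when there is none).
    """
    anytime = False
    first_hit: Optional[pd.Timestamp] = None
    if len(pfpoints):
        hit = (pfpoints["paired"].to_numpy(dtype=bool)
               & (pfpoints["peep"].to_numpy(dtype=float) >= PEEP_THRESHOLD_CMH2O)
               & (pfpoints["pf"].to_numpy(dtype=float) < PF_THRESHOLD_MMHG))
        if hit.any():
            anytime = True
            first_hit = pfpoints.loc[hit, "time"].min()

    episode = None
    if len(windows):
        complete = windows[windows["complete"]]
        qual = complete["qualifies"].to_numpy(dtype=bool)
        if qual.any():
            i0 = int(np.argmax(qual))                       # first run start
            run = qual[i0:]
            stop = np.argmin(run) if not run.all() else len(run)
            row = complete.iloc[i0]
            episode = Episode(stay_id=str(row["stay_id"]), onset=row["start"],
                              onset_index=int(row["index"]), n_consecutive=int(stop))
    return episode, anytime, first_hit


@dataclass(frozen=True)
class PersistenceResult:
    persistence_class: PersistenceClass
    stratum: Stratum
    onset: pd.Timestamp
    n_consecutive: int
    excluded_early_death: bool
    death_within_48_72h: bool


def classify_persistence(
    episode: Optional[Episode],
    stay,
    *,
    anytime: bool = False,
    first_hit_time: Optional[pd.Timestamp] = None,
) -> Optional[PersistenceResult]:
    """Grade a stay's persistence class, stratum and exclusion flags.

    ``stay`` is a mapping/Series with ``death_time`` (NaT when alive).
    Returns None when the stay meets no screening criterion at all.
    """
    death = stay.get("death_time") if hasattr(stay, "get") else stay["death_time"]
    death = pd.Timestamp(death) if pd.notna(death) else None

    if episode is None:
        if not anytime:
            return None
        onset = first_hit_time
        excluded = death is not None and death < onset + pd.Timedelta(hours=48)
        return PersistenceResult(PersistenceClass.ANYTIME_ONLY, Stratum.H0_24,
                                 onset, 0, excluded, False)

    onset = episode.onset
    n = episode.n_consecutive
    death_48_72 = (death is not None
                   and onset + pd.Timedelta(hours=48) <= death < onset + pd.Timedelta(hours=72))
    if n >= 3 or (n >= 2 and death_48_72):
        cls, stratum = PersistenceClass.H72, Stratum.H48_72PLUS
    elif n >= 2:
        cls, stratum = PersistenceClass.H48, Stratum.H24_48
    else:
        cls, stratum = PersistenceClass.H24, Stratum.H0_24
    excluded = death is not None and death < onset + pd.Timedelta(hours=48)
    return PersistenceResult(cls, stratum, onset, n, excluded, death_48_72)


def screen_cohort(
    bundle: CohortBundle,
    *,
    tolerance_h: float = DEFAULT_PAIRING_TOLERANCE_H,
    pfpoints: Optional[pd.DataFrame] = None,
    windows: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Screen every subject; one row per subject, first qualifying stay.

    Harmonised ``pfpoints``/``windows`` may be supplied to avoid recomputing
    them; otherwise they are derived from the bundle. Output is sorted by
    subject_id, which together with deterministic upstream steps makes
    identical inputs produce identical bytes.
    """
    if pfpoints is None or windows is None:
        pfpoints, windows = harmonize_cohort(bundle.stays, bundle.events, tolerance_h)

    # -- anytime screen: first paired measurement with P/F<300 & PEEP>=5 ----
    if len(pfpoints):
        hit = (pfpoints["paired"].to_numpy(dtype=bool)
               & (pfpoints["peep"].to_numpy(dtype=float) >= PEEP_THRESHOLD_CMH2O)
               & (pfpoints["pf"].to_numpy(dtype=float) < PF_THRESHOLD_MMHG))
        first_hit = pfpoints.loc[hit].groupby("stay_id")["time"].min()
    else:
        first_hit = pd.Series(dtype="datetime64[ns]")

    # -- episodes: first run of consecutive qualifying complete windows -----
    episodes: dict[str, Episode] = {}
    wc = windows[windows["complete"]] if len(windows) else windows
    if len(wc):
        sid = wc["stay_id"].to_numpy()
        q = wc["qualifies"].to_numpy(dtype=bool)
        new_stay = np.r_[True, sid[1:] != sid[:-1]]
        q_prev = np.r_[False, q[:-1]]
        q_prev[new_stay] = False
        run_start = q & ~q_prev
        run_id = np.cumsum(run_start)                    # 1-based over q runs
        run_len = np.bincount(run_id[q])                 # length per run id
        starts = np.flatnonzero(run_start)
        if len(starts):
            # first run per stay: stays are contiguous, runs in index order
            first_mask = np.r_[True, sid[starts][1:] != sid[starts][:-1]]
            for p in starts[first_mask]:
                episodes[sid[p]] = Episode(
                    stay_id=str(sid[p]), onset=wc["start"].iloc[p],
                    onset_index=int(wc["index"].iloc[p]),
                    n_consecutive=int(run_len[run_id[p]]))

    # -- ventilation flags relative to onset --------------------------------
    onset_by_stay: dict[str, pd.Timestamp] = dict(first_hit.items())
    onset_by_stay.update({s: e.onset for s, e in episodes.items()})
    vent_at_by_stay: dict[str, bool] = {}
    vent_after_by_stay: dict[str, bool] = {}
    if len(bundle.events):
        vent = bundle.events[(bundle.events["kind"] == ObsKind.VENT.value)
                             & (bundle.events["value"] == 1.0)]
        if len(vent):
            onset = vent["stay_id"].map(onset_by_stay)
            ok = onset.notna()
            t = vent["time"]
            after = ok & (t >= onset)
            at = after & (t < onset + pd.Timedelta(hours=WINDOW_H))
            vent_at_by_stay = vent.loc[at].groupby("stay_id").size().astype(bool).to_dict()
            vent_after_by_stay = vent.loc[after].groupby("stay_id").size().astype(bool).to_dict()

    # -- assemble one row per stay, classify, keep first stay per subject ---
    rows = []
    stays_sorted = bundle.stays.sort_values(["subject_id", "icu_in", "stay_id"], kind="stable")
    for stay in stays_sorted.itertuples(index=False):
        sid = stay.stay_id
        anytime = sid in first_hit.index
        res = classify_persistence(
            episodes.get(sid), {"death_time": stay.death_time}, anytime=anytime,
            first_hit_time=first_hit[sid] if anytime else None)
        if res is None:
            continue
        rows.append({
            "subject_id": stay.subject_id, "stay_id": sid, "onset": res.onset,
            "n_consecutive": res.n_consecutive, "anytime": anytime,
            "persistence_class": res.persistence_class.value, "stratum": res.stratum.value,
            "excluded_early_death": res.excluded_early_death,
            "death_within_48_72h": res.death_within_48_72h,
            "vent_at_onset": vent_at_by_stay.get(sid, False),
            "vent_after_onset": vent_after_by_stay.get(sid, False),
        })

    if not rows:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    df = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    # first qualifying stay per subject (stays were pre-sorted by icu_in)
    df = df.drop_duplicates(subset="subject_id", keep="first")
    df = df.sort_values("subject_id", kind="stable").reset_index(drop=True)
    logger.info("screen: %d subjects screened positive; cascade %s",
                len(df), cascade_counts(df))
    return df


def in_window(results: pd.DataFrame, window: str) -> pd.Series:
    """Boolean mask over screen results for membership in a named cohort.

    ``window`` is one of ``anytime, 24, 48, 72`` (string or int). Members of
    a stricter cohort belong to every looser one.
    """
    cls = results["persistence_class"]
    w = str(window).lower()
    if w in ("anytime", "any"):
        return results["anytime"].astype(bool)
    rank = {"24": 1, "48": 2, "72": 3}[w.removeprefix("h")]
    order = {c.value: i for i, c in enumerate(_CLASS_ORDER)}
    return cls.map(order).ge(rank)


def cascade_counts(results: pd.DataFrame) -> dict[str, int]:
    """Subject counts of the nested screening cohorts (consort-style)."""
    return {w: int(in_window(results, w).sum()) for w in ("anytime", "24", "48", "72")}
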