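"""Persistence episode detection, classification, and cohort nesting."""

import numpy as np
import pandas as pd
import pytest

from ardscreen.ehr_model import CohortBundle
from ardscreen.screen import (PersistenceClass, Stratum, cascade_counts,
                              classify_persistence, find_first_episode,
                              in_window, screen_cohort)
from ardscreen.synth import simulate_cohort, whole_icu_calibration

from conftest import T, hypoxic_stay_events, make_bundle


def _windows(pattern, stay_id="S1", complete=None):
    """Build a windows table from a qualify pattern like [True, True, False]."""
    n = len(pattern)
    complete = [True] * n if complete is None else complete
    return pd.DataFrame({
        "stay_id": stay_id, "index": range(n),
        "start": [T(24 * i) for i in range(n)],
        "n_eligible": [2] * n,
        "mean_pf": [150.0 if q else 350.0 for q in pattern],
        "qualifies": list(pattern), "complete": complete,
    })


EMPTY_PF = pd.DataFrame(columns=["stay_id", "time", "pf", "peep", "paired"])


def _stay(death_h=None):
    return {"stay_id": "S1", "death_time": T(death_h) if death_h is not None else pd.NaT}


def test_leading_run_detected():
    ep, anytime, _ = find_first_episode(_windows([True, True, True, False]), EMPTY_PF)
    assert ep.onset == T(0) and ep.n_consecutive == 3


def test_first_run_retained_even_when_later_run_is_longer():
    ep, _, _ = find_first_episode(_windows([False, True, False, True, True, True]), EMPTY_PF)
    assert ep.onset == T(24) and ep.n_consecutive == 1


def test_single_qualifying_measurement_sets_anytime_without_episode():
    pf = pd.DataFrame({"stay_id": ["S1"], "time": [T(5)], "pf": [250.0],
                       "peep": [6.0], "paired": [True]})
    ep, anytime, first_hit = find_first_episode(_windows([False, False]), pf)
    assert ep is None and anytime and first_hit == T(5)


def test_trailing_partial_window_does_not_extend_a_run():
    ep, _, _ = find_first_episode(
        _windows([True, True, True], complete=[True, True, False]), EMPTY_PF)
    assert ep.n_consecutive == 2


def test_three_windows_grade_h72():
    res = classify_persistence(find_first_episode(_windows([True] * 3), EMPTY_PF)[0], _stay())
    assert res.persistence_class is PersistenceClass.H72
    assert res.stratum is Stratum.H48_72PLUS


def test_two_windows_with_death_on_day3_grade_h72():
    ep = find_first_episode(_windows([True, True], complete=[True, True]), EMPTY_PF)[0]
    res = classify_persistence(ep, _stay(death_h=60))
    assert res.persistence_class is PersistenceClass.H72
    assert res.death_within_48_72h


@pytest.mark.parametrize("death_h,expected", [
    (47.9, PersistenceClass.H48),   # death before onset+48h: variant cannot fire
    (72.0, PersistenceClass.H48),   # boundary: death at exactly +72h is outside
    (None, PersistenceClass.H48),   # survivor with 2 windows
])
def test_death_on_day3_variant_boundaries(death_h, expected):
    ep = find_first_episode(_windows([True, True]), EMPTY_PF)[0]
    res = classify_persistence(ep, _stay(death_h=death_h))
    assert res.persistence_class is expected


def test_early_death_flagged_for_exclusion():
    ep = find_first_episode(_windows([True]), EMPTY_PF)[0]
    res = classify_persistence(ep, _stay(death_h=30))
    assert res.excluded_early_death
    assert res.persistence_class is PersistenceClass.H24


def test_broken_run_restarts_persistence_count():
    ep, _, _ = find_first_episode(_windows([True, False, True, True, True]), EMPTY_PF)
    assert ep.n_consecutive == 1  # the first run, not the later longer one


def test_no_criteria_returns_none():
    ep, anytime, _ = find_first_episode(_windows([False, False]), EMPTY_PF)
    assert ep is None and not anytime
    assert classify_persistence(ep, _stay(), anytime=False) is None


# ---------------------------------------------------------------------------
# cohort level

def test_first_qualifying_stay_per_subject_is_retained():
    stays = [("S1", "P1", 0, 100, None), ("S2", "P1", 200, 300, None)]
    events = hypoxic_stay_events("S1", 4) + [
        ("S2", 200 + t, k, v) for _, t, k, v in hypoxic_stay_events("S2", 4)]
    bundle = make_bundle(stays, events)
    res = screen_cohort(bundle)
    assert len(res) == 1
    assert res["stay_id"].iloc[0] == "S1"


def test_empty_bundle_gives_empty_table_and_zero_cascade():
    bundle = make_bundle([], [("S0", 1, "pao2_mmHg", 80)][:0])
    res = screen_cohort(bundle)
    assert len(res) == 0
    assert cascade_counts(res) == {"anytime": 0, "24": 0, "48": 0, "72": 0}


def test_cascade_counts_match_brute_force_on_random_cohort():
    bundle = simulate_cohort(whole_icu_calibration(n_subjects=120, seed=3))
    res = screen_cohort(bundle)
    counts = cascade_counts(res)
    order = {"ANYTIME_ONLY": 0, "H24": 1, "H48": 2, "H72": 3}
    ranks = res["persistence_class"].map(order)
    assert counts["anytime"] == len(res)
    assert counts["24"] == int((ranks >= 1).sum())
    assert counts["48"] == int((ranks >= 2).sum())
    assert counts["72"] == int((ranks >= 3).sum())
    assert counts["anytime"] >= counts["24"] >= counts["48"] >= counts["72"]


def test_monotone_nesting_of_screen_cohorts():
    bundle = simulate_cohort(whole_icu_calibration(n_subjects=200, seed=9))
    res = screen_cohort(bundle)
    sets = {w: set(res.loc[in_window(res, w), "subject_id"]) for w in ("anytime", "24", "48", "72")}
    assert sets["72"] <= sets["48"] <= sets["24"] <= sets["anytime"]


def test_screen_is_deterministic_bytes(tmp_path):
    from ardscreen.ehr_model import write_table
    bundle = simulate_cohort(whole_icu_calibration(n_subjects=60, seed=4))
    for i in (1, 2):
        write_table(screen_cohort(bundle), tmp_path / f"r{i}.csv")
    assert (tmp_path / "r1.csv").read_bytes() == (tmp_path / "r2.csv").read_bytes()


def test_cohort_screen_matches_per_stay_reference():
    """The vectorised cohort path agrees with the per-stay operations."""
    from ardscreen.harmonize import harmonize_cohort
    bundle = simulate_cohort(whole_icu_calibration(n_subjects=80, seed=12))
    pf, win = harmonize_cohort(bundle.stays, bundle.events)
    res = screen_cohort(bundle, pfpoints=pf, windows=win)
    got = {r.stay_id: (r.persistence_class, r.n_consecutive, r.onset)
           for r in res.itertuples(index=False)}
    for stay in bundle.stays.itertuples(index=False):
        ep, anytime, first_hit = find_first_episode(
            win[win["stay_id"] == stay.stay_id], pf[pf["stay_id"] == stay.stay_id])
        ref = classify_persistence(ep, stay._asdict(), anytime=anytime,
                                   first_hit_time=first_hit)
        if ref is None:
            assert stay.stay_id not in got
        else:
            assert got[stay.stay_id] == (ref.persistence_class.value,
                                         ref.n_consecutive, ref.onset)


def test_vent_status_columns_reflect_vent_events():
    stays = [("S1", "P1", 0, 96, None)]
    events = hypoxic_stay_events("S1", 4) + [("S1", 2, "vent_flag", 1)]
    res = screen_cohort(make_bundle(stays, events))
    assert bool(res["vent_at_onset"].iloc[0]) and bool(res["vent_after_onset"].iloc[0])
    # ventilation starting on day 2: after onset but not in the onset window
    events = hypoxic_stay_events("S1", 4) + [("S1", 30, "vent_flag", 1)]
    res = screen_cohort(make_bundle(stays, events))
    assert not bool(res["vent_at_onset"].iloc[0]) and bool(res["vent_after_onset"].iloc[0])
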