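"""Pair P/F ratios with contemporaneous PEEP and aggregate into 24-h windows.

The physiologic screen needs, for every 24-h window of an ICU stay, the mean
PaO2/FiO2 ratio over measurements that were *contemporaneous* with a PEEP of
at least 5 cm H2O. Two harmonisation steps produce that:

1. :func:`pair_pf_with_peep` — PaO2 is matched to the FiO2 of the same
   blood-gas record (identical timestamp, or nearest within 5 minutes), giving
   a P/F point; each P/F point is then paired with the nearest-in-time PEEP
   within a configurable tolerance (default ±2 h, ties broken toward the
   earlier PEEP). Points with no PEEP in tolerance are kept but marked
   unpaired and excluded from window means.
2. :func:`build_day_windows` — non-overlapping 24-h windows anchored at ICU
   admission tile the stay; each window's ``mean_pf`` averages the P/F points
   whose paired PEEP is ≥ 5 cm H2O, and the window qualifies when that mean
   is below 300 mm Hg.

Windows are anchored at admission rather than at first hypoxaemia so that the
windowing is deterministic and independent of the quantity being detected;
hypoxaemia onset is defined downstream as the start of the first qualifying
window.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .ehr_model import InvalidMeasurementError, ObsKind

logger = logging.getLogger(__name__)

PF_THRESHOLD_MMHG = 300.0
PEEP_THRESHOLD_CMH2O = 5.0
GAS_MATCH_TOLERANCE_H = 5.0 / 60.0  # PaO2 ↔ FiO2 of the same blood-gas draw
DEFAULT_PAIRING_TOLERANCE_H = 2.0   # P/F ↔ PEEP contemporaneity
WINDOW_H = 24.0

PF_COLUMNS = ["stay_id", "time", "pf", "peep", "paired"]
WINDOW_COLUMNS = ["stay_id", "index", "start", "n_eligible", "mean_pf", "qualifies", "complete"]


def _hours(times: pd.Series | np.ndarray) -> np.ndarray:
    """datetime64[ns] → float hours since the epoch."""
    return np.asarray(times, dtype="datetime64[ns]").astype("int64") / 3.6e12


def _nearest(ref: np.ndarray, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index into sorted ``ref`` of the value nearest each ``query``.

    Exact distance ties are broken toward the *earlier* reference value.
    Returns (indices, absolute deltas); ``ref`` must be non-empty.
    """
    idx = np.searchsorted(ref, query)
    lo = np.clip(idx - 1, 0, len(ref) - 1)
    hi = np.clip(idx, 0, len(ref) - 1)
    d_lo = np.abs(query - ref[lo])
    d_hi = np.abs(ref[hi] - query)
    take_lo = d_lo <= d_hi  # tie → earlier
    out = np.where(take_lo, lo, hi)
    return out, np.where(take_lo, d_lo, d_hi)


def pair_pf_with_peep(
    events: pd.DataFrame,
    tolerance_h: float = DEFAULT_PAIRING_TOLERANCE_H,
) -> pd.DataFrame:
    """Build P/F points with contemporaneous PEEP for one stay's events.

    Parameters
    ----------
    events
        Events of a single stay (columns ``stay_id, time, kind, value``),
        sorted by time.
    tolerance_h
        Maximum |t(P/F) − t(PEEP)| in hours for a PEEP to count as
        contemporaneous.

    Returns
    -------
    DataFrame with columns ``stay_id, time, pf, peep, paired``; ``peep`` is
    NaN and ``paired`` False when no PEEP lies within tolerance. PaO2 values
    with no FiO2 within 5 minutes are dropped (count in ``attrs['n_dropped']``).

    Raises
    ------
    InvalidMeasurementError
        if a matched FiO2 is zero or negative.
    """
    if len(events) == 0:
        out = pd.DataFrame(columns=PF_COLUMNS)
        out.attrs["n_dropped"] = 0
        return out
    stay_id = events["stay_id"].iloc[0]
    kind = events["kind"].to_numpy()
    t = _hours(events["time"])
    v = events["value"].to_numpy(dtype=float)

    t_pao2, v_pao2 = t[kind == ObsKind.PAO2.value], v[kind == ObsKind.PAO2.value]
    t_fio2, v_fio2 = t[kind == ObsKind.FIO2.value], v[kind == ObsKind.FIO2.value]
    t_peep, v_peep = t[kind == ObsKind.PEEP.value], v[kind == ObsKind.PEEP.value]

    if len(t_pao2) == 0 or len(t_fio2) == 0:
        out = pd.DataFrame(columns=PF_COLUMNS)
        out.attrs["n_dropped"] = int(len(t_pao2))
        return out

    order = np.argsort(t_fio2, kind="stable")
    t_fio2, v_fio2 = t_fio2[order], v_fio2[order]
    fi_idx, fi_delta = _nearest(t_fio2, t_pao2)
    matched = fi_delta <= GAS_MATCH_TOLERANCE_H + 1e-12
    n_dropped = int((~matched).sum())
    if n_dropped:
        logger.warning("stay %s: dropped %d PaO2 value(s) with no FiO2 within 5 min",
                       stay_id, n_dropped)
    t_pf = t_pao2[matched]
    fio2 = v_fio2[fi_idx[matched]]
    if np.any(fio2 <= 0):
        raise InvalidMeasurementError(f"stay {stay_id}: FiO2 <= 0 in matched blood gas")
    pf = v_pao2[matched] / fio2

    if len(t_peep):
        order = np.argsort(t_peep, kind="stable")
        t_peep, v_peep = t_peep[order], v_peep[order]
        pe_idx, pe_delta = _nearest(t_peep, t_pf)
        paired = pe_delta <= tolerance_h + 1e-12
        peep = np.where(paired, v_peep[pe_idx], np.nan)
    else:
        paired = np.zeros(len(t_pf), dtype=bool)
        peep = np.full(len(t_pf), np.nan)

    out = pd.DataFrame({
        "stay_id": stay_id,
        "time": pd.to_datetime((t_pf * 3.6e12).round().astype("int64")),
        "pf": pf,
        "peep": peep,
        "paired": paired,
    })
    out.attrs["n_dropped"] = n_dropped
    return out


def build_day_windows(pfpoints: pd.DataFrame, stay) -> pd.DataFrame:
    """Aggregate one stay's P/F points into admission-anchored 24-h windows.

    ``stay`` is a mapping/Series with ``stay_id, icu_in, icu_out``. Windows
    tile ``[icu_in, icu_out)`` in 24-h steps (the trailing window may be
    partial; ``complete`` marks full windows). ``mean_pf`` averages points
    with paired PEEP ≥ 5 cm H2O; a window with no eligible point has
    ``mean_pf`` NaN and does not qualify. ``qualifies`` is
    ``mean_pf < 300 mm Hg``.
    """
    icu_in = pd.Timestamp(stay["icu_in"])
    icu_out = pd.Timestamp(stay["icu_out"])
    stay_h = (icu_out - icu_in) / pd.Timedelta(hours=1)
    n_windows = max(1, math.ceil(stay_h / WINDOW_H - 1e-9))

    mean_pf = np.full(n_windows, np.nan)
    n_elig = np.zeros(n_windows, dtype=int)
    if len(pfpoints):
        hrs = (_hours(pfpoints["time"]) - _hours(pd.Series([icu_in]))[0])
        elig = (pfpoints["paired"].to_numpy(dtype=bool)
                & (pfpoints["peep"].to_numpy(dtype=float) >= PEEP_THRESHOLD_CMH2O)
                & (hrs >= 0) & (hrs < stay_h))
        widx = np.floor(hrs[elig] / WINDOW_H).astype(int)
        widx = np.clip(widx, 0, n_windows - 1)
        pf = pfpoints["pf"].to_numpy(dtype=float)[elig]
        counts = np.bincount(widx, minlength=n_windows)
        sums = np.bincount(widx, weights=pf, minlength=n_windows)
        has = counts > 0
        mean_pf[has] = sums[has] / counts[has]
        n_elig = counts

    idx = np.arange(n_windows)
    return pd.DataFrame({
        "stay_id": stay["stay_id"],
        "index": idx,
        "start": icu_in + pd.to_timedelta(idx * WINDOW_H, unit="h"),
        "n_eligible": n_elig,
        "mean_pf": mean_pf,
        "qualifies": ~np.isnan(mean_pf) & (mean_pf < PF_THRESHOLD_MMHG),
        "complete": (idx + 1) * WINDOW_H <= stay_h + 1e-9,
    })


def _stay_core(
    t: np.ndarray, kind: np.ndarray, v: np.ndarray,
    t0_h: float, stay_h: float, tolerance_h: float,
):
    """Numpy core shared by the cohort fast path: one stay in, arrays out.

    Returns ``(t_pf, pf, peep, paired, mean_pf, n_elig)`` where the last two
    are per-window aggregates. Mirrors :func:`pair_pf_with_peep` +
    :func:`build_day_windows` exactly (asserted by an equivalence test).
    """
    n_windows = max(1, math.ceil(stay_h / WINDOW_H - 1e-9))
    empty_w = (np.full(n_windows, np.nan), np.zeros(n_windows, dtype=int))

    t_pao2, v_pao2 = t[kind == ObsKind.PAO2.value], v[kind == ObsKind.PAO2.value]
    t_fio2, v_fio2 = t[kind == ObsKind.FIO2.value], v[kind == ObsKind.FIO2.value]
    t_peep, v_peep = t[kind == ObsKind.PEEP.value], v[kind == ObsKind.PEEP.value]
    if len(t_pao2) == 0 or len(t_fio2) == 0:
        z = np.array([])
        return z, z, z, np.array([], dtype=bool), *empty_w

    order = np.argsort(t_fio2, kind="stable")
    t_fio2, v_fio2 = t_fio2[order], v_fio2[order]
    fi_idx, fi_delta = _nearest(t_fio2, t_pao2)
    matched = fi_delta <= GAS_MATCH_TOLERANCE_H + 1e-12
    t_pf = t_pao2[matched]
    fio2 = v_fio2[fi_idx[matched]]
    if np.any(fio2 <= 0):
        raise InvalidMeasurementError("FiO2 <= 0 in matched blood gas")
    pf = v_pao2[matched] / fio2

    if len(t_peep):
        order = np.argsort(t_peep, kind="stable")
        t_peep, v_peep = t_peep[order], v_peep[order]
        pe_idx, pe_delta = _nearest(t_peep, t_pf)
        paired = pe_delta <= tolerance_h + 1e-12
        peep = np.where(paired, v_peep[pe_idx], np.nan)
    else:
        paired = np.zeros(len(t_pf), dtype=bool)
        peep = np.full(len(t_pf), np.nan)

    hrs = t_pf - t0_h
    elig = paired & (peep >= PEEP_THRESHOLD_CMH2O) & (hrs >= 0) & (hrs < stay_h)
    mean_pf, n_elig = empty_w
    if elig.any():
        widx = np.clip(np.floor(hrs[elig] / WINDOW_H).astype(int), 0, n_windows - 1)
        counts = np.bincount(widx, minlength=n_windows)
        sums = np.bincount(widx, weights=pf[elig], minlength=n_windows)
        has = counts > 0
        mean_pf[has] = sums[has] / counts[has]
        n_elig = counts
    return t_pf, pf, peep, paired, mean_pf, n_elig


def harmonize_cohort(
    stays: pd.DataFrame,
    events: pd.DataFrame,
    tolerance_h: float = DEFAULT_PAIRING_TOLERANCE_H,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run pairing and windowing for every stay.

    Returns ``(pfpoints, windows)`` concatenated across stays. Stays with no
    events still get their (all-undefined) windows. Equivalent to calling
    :func:`pair_pf_with_peep` and :func:`build_day_windows` per stay, but on
    flat arrays for speed on large cohorts.
    """
    ev_sid = events["stay_id"].to_numpy() if len(events) else np.array([], dtype=object)
    ev_t = _hours(events["time"]) if len(events) else np.array([])
    ev_kind = events["kind"].to_numpy() if len(events) else np.array([], dtype=object)
    ev_val = events["value"].to_numpy(dtype=float) if len(events) else np.array([])
    # events are sorted by (stay_id, time); locate each stay's slice
    bounds: dict[str, tuple[int, int]] = {}
    if len(ev_sid):
        uniq, starts = np.unique(ev_sid, return_index=True)
        order = np.argsort(starts)
        starts = starts[order]
        uniq = uniq[order]
        ends = np.append(starts[1:], len(ev_sid))
        bounds = {s: (int(a), int(b)) for s, a, b in zip(uniq, starts, ends)}

    pf_sid: list[np.ndarray] = []
    pf_parts: list[tuple] = []
    win_sid: list[np.ndarray] = []
    win_parts: list[tuple] = []
    icu_in_h = _hours(stays["icu_in"]) if len(stays) else np.array([])
    icu_out_h = _hours(stays["icu_out"]) if len(stays) else np.array([])
    for i, sid in enumerate(stays["stay_id"].to_numpy() if len(stays) else []):
        a, b = bounds.get(sid, (0, 0))
        stay_h = icu_out_h[i] - icu_in_h[i]
        t_pf, pf, peep, paired, mean_pf, n_elig = _stay_core(
            ev_t[a:b], ev_kind[a:b], ev_val[a:b], icu_in_h[i], stay_h, tolerance_h)
        pf_sid.append(np.full(len(t_pf), sid, dtype=object))
        pf_parts.append((t_pf, pf, peep, paired))
        nw = len(mean_pf)
        win_sid.append(np.full(nw, sid, dtype=object))
        win_parts.append((np.arange(nw), np.full(nw, icu_in_h[i]), n_elig, mean_pf,
                          np.full(nw, stay_h)))

    if pf_parts:
        t_all = np.concatenate([p[0] for p in pf_parts])
        pfpoints = pd.DataFrame({
            "stay_id": np.concatenate(pf_sid),
            "time": pd.to_datetime((t_all * 3.6e12).round().astype("int64")),
            "pf": np.concatenate([p[1] for p in pf_parts]),
            "peep": np.concatenate([p[2] for p in pf_parts]),
            "paired": np.concatenate([p[3] for p in pf_parts]),
        })
        idx = np.concatenate([w[0] for w in win_parts])
        start_h = np.concatenate([w[1] for w in win_parts]) + idx * WINDOW_H
        mean_pf = np.concatenate([w[3] for w in win_parts])
        stay_hs = np.concatenate([w[4] for w in win_parts])
        windows = pd.DataFrame({
            "stay_id": np.concatenate(win_sid),
            "index": idx,
            "start": pd.to_datetime((start_h * 3.6e12).round().astype("int64")),
            "n_eligible": np.concatenate([w[2] for w in win_parts]),
            "mean_pf": mean_pf,
            "qualifies": ~np.isnan(mean_pf) & (mean_pf < PF_THRESHOLD_MMHG),
            "complete": (idx + 1) * WINDOW_H <= stay_hs + 1e-9,
        })
    else:
        pfpoints = pd.DataFrame(columns=PF_COLUMNS)
        windows = pd.DataFrame(columns=WINDOW_COLUMNS)
    logger.info("harmonize: %d stays -> %d P/F points, %d windows",
                len(stays), len(pfpoints), len(windows))
    return pfpoints, windows
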