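"""Cardiac preprocessing: beat times -> BPM -> trial-wise bradycardia (Dhr).

Anticipatory heart-rate deceleration (bradycardia) indexes a freezing-like
defensive state.  It is quantified per trial as the mean baseline-corrected
heart rate over the 5-7 s window after anticipation onset, with the baseline
taken as the mean heart rate over the 1 s immediately preceding onset; more
negative Dhr means stronger bradycardia.  Only long-AMI trials are scored
because the cardiac response develops slowly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Plausible human inter-beat-interval range (s); values outside flag the trial.
IBI_BOUNDS = (0.33, 2.0)
#: Largest tolerated gap (s) between BPM stamps inside a scoring window.
#: Matches the upper plausible IBI: a slow but regular heart is fine, a
#: longer gap means missed beats.
MAX_GAP = 2.0
GRID_HZ = 10.0
RT_FLOOR = 0.200  # s; faster active responses are anticipations, excluded


def ibi_to_bpm(beat_times) -> tuple[np.ndarray, np.ndarray]:
    """Convert beat times to an instantaneous BPM series (BPM = 60 / IBI).

    Each inter-beat interval yields one BPM value, timestamped at the
    interval's second beat.  Returns ``(times, bpm)``.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.ndim != 1 or beat_times.size < 2:
        raise DataError("need at least 2 beats to form a BPM series")
    ibis = np.diff(beat_times)
    if np.any(ibis <= 0):
        raise DataError("beat times must be strictly increasing")
    return beat_times[1:], 60.0 / ibis


def _window_mean(
    stamp_times: np.ndarray, bpm: np.ndarray, lo: float, hi: float, grid_hz: float
) -> float:
    """Mean of the linearly interpolated BPM series over [lo, hi]."""
    grid = np.arange(lo, hi + 0.5 / grid_hz, 1.0 / grid_hz)
    return float(np.mean(np.interp(grid, stamp_times, bpm)))


def compute_dhr(
    beat_times,
    onset: float,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    dhr_window: tuple[float, float] = (5.0, 7.0),
    grid_hz: float = GRID_HZ,
) -> dict:
    """Score one trial's bradycardia from its beat times.

    Dhr = mean BPM over ``onset + dhr_window`` minus mean BPM over
    ``onset + baseline_window``, computed on a ``grid_hz`` linear
    interpolation of the beat-stamped BPM series.  Trials whose windows are
    not covered by the trace, contain an implausible IBI, or have stamp gaps
    above :data:`MAX_GAP` are flagged ``quality='bad'`` with ``dhr=nan``
    instead of raising.
    """
    record = {"baseline_bpm": np.nan, "dhr": np.nan, "quality": "bad", "reason": ""}
    try:
        times, bpm = ibi_to_bpm(beat_times)
    except DataError as exc:
        record["reason"] = str(exc)
        return record

    lo = onset + baseline_window[0]
    hi = onset + dhr_window[1]
    if times[0] > lo or times[-1] < hi:
        record["reason"] = "trace does not cover scoring windows"
        return record
    in_span = (np.asarray(beat_times) >= lo - IBI_BOUNDS[1]) & (
        np.asarray(beat_times) <= hi + IBI_BOUNDS[1]
    )
    span_ibis = np.diff(np.asarray(beat_times, dtype=float)[in_span])
    if span_ibis.size and (
        np.any(span_ibis < IBI_BOUNDS[0]) or np.any(span_ibis > IBI_BOUNDS[1])
    ):
        record["reason"] = "implausible inter-beat interval near scoring windows"
        return record
    stamps_in = times[(times >= lo) & (times <= hi)]
    if stamps_in.size and np.max(np.diff(np.concatenate([[lo], stamps_in, [hi]]))) > MAX_GAP:
        record["reason"] = "stamp gap exceeds tolerance inside scoring windows"
        return record

    baseline = _window_mean(times, bpm, onset + baseline_window[0], onset + baseline_window[1], grid_hz)
    window = _window_mean(times, bpm, onset + dhr_window[0], onset + dhr_window[1], grid_hz)
    record.update(baseline_bpm=baseline, dhr=window - baseline, quality="ok", reason="")
    return record


def score_trials(trials: pd.DataFrame, traces: dict) -> pd.DataFrame:
    """Attach ``dhr``, ``baseline_bpm`` and ``quality`` columns to a trial table.

    ``traces`` maps ``(subject, run, trial)`` to beat-time arrays (run clock);
    long trials without a trace are flagged bad, short trials are left
    unscored (``quality='short'``).
    """
    out = trials.copy()
    dhr = np.full(len(out), np.nan)
    baseline = np.full(len(out), np.nan)
    quality = np.full(len(out), "short", dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.is_long:
            continue
        beats = traces.get((row.subject, row.run, row.trial))
        if beats is None:
            quality[i] = "bad"
            continue
        rec = compute_dhr(beats, row.onset)
        dhr[i] = rec["dhr"]
        baseline[i] = rec["baseline_bpm"]
        quality[i] = rec["quality"]
    out["dhr"] = dhr
    out["baseline_bpm"] = baseline
    out["quality"] = quality
    return out


def is_active_response(choice, action_context) -> np.ndarray:
    """Button presses: approach in the active context, avoid in the passive one."""
    choice = np.asarray(choice, dtype=object)
    ac = np.asarray(action_context, dtype=object)
    return ((choice == "approach") & (ac == "active")) | (
        (choice == "avoid") & (ac == "passive")
    )


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Trial-wise exclusion rules, applied in order.

    1. short-AMI trials (cardiac window does not fit the anticipation screen);
    2. trials with poor heart-rate data (``quality != 'ok'``);
    3. active-response trials with RT below 200 ms.

    Returns the analysis set and a per-rule exclusion report whose counts sum
    to the number of dropped rows.
    """
    report = {"n_input": int(len(table))}
    keep = table["is_long"].to_numpy(dtype=bool)
    report["short_ami"] = int((~keep).sum())

    good = table["quality"].to_numpy(dtype=object) == "ok" if "quality" in table else np.ones(len(table), bool)
    report["poor_heart_rate"] = int((keep & ~good).sum())
    keep &= good

    if "rt" in table and "choice" in table:
        active = is_active_response(table["choice"], table["action_context"])
        rt = table["rt"].to_numpy(dtype=float)
        fast = active & (rt < RT_FLOOR)
        report["fast_rt"] = int((keep & fast).sum())
        keep &= ~fast
    else:
        report["fast_rt"] = 0

    out = table.loc[keep].copy()
    report["n_retained"] = int(len(out))
    return out, report


def standardize_predictors(
    table: pd.DataFrame,
    dhr_col: str = "dhr",
    stats: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Z-score continuous predictors pooled across all trials of all subjects.

    Adds ``z_money``, ``z_shocks``, ``z_dms`` (money - shocks, differenced on
    the raw levels first, then standardized), ``z_dhr`` and the sum-to-zero
    action-context code ``ac_code`` (-1 active, +1 passive).  When a ``choice``
    column is present a ``choice_code`` (+1 approach, -1 avoid) is added too.

    Pass ``stats`` (as returned by a previous call) to re-use frozen pooled
    means/SDs, e.g. when building regressors for new trials.
    """
    out = table.copy()
    out["dms"] = out["money"].astype(float) - out["shocks"].astype(float)
    cont = {"money": "z_money", "shocks": "z_shocks", "dms": "z_dms", dhr_col: "z_dhr"}
    if stats is None:
        stats = {}
        for col in cont:
            x = out[col].to_numpy(dtype=float)
            mean, sd = float(np.nanmean(x)), float(np.nanstd(x))
            if not np.isfinite(sd) or sd == 0:
                raise DataError(f"cannot standardize {col!r}: pooled SD is zero")
            stats[col] = (mean, sd)
    for col, zcol in cont.items():
        mean, sd = stats[col]
        out[zcol] = (out[col].to_numpy(dtype=float) - mean) / sd
    out["ac_code"] = np.where(out["action_context"].to_numpy(dtype=object) == "passive", 1.0, -1.0)
    if "choice" in out:
        out["choice_code"] = np.where(out["choice"].to_numpy(dtype=object) == "approach", 1.0, -1.0)
    return out, stats
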