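"""Behavioral-state segmentation from wheel velocity.

A velocity trace is binarized into run/rest, then five classes of 10-s
analysis windows are extracted around qualifying locomotion bouts:

* ``onset``        — 5 s of rest + the first 5 s of running;
* ``locomotion``   — the middle 10 s of a bout of at least 20 s preceded by
                     at least 60 s of rest;
* ``offset``       — the last 5 s of running + the first 5 s of rest, for
                     bouts of at least 20 s with at least 10 s post-rest;
* ``initial_rest`` — the first 10 s of rest after a bout of at least 5 s
                     with at least 60 s of post-rest;
* ``sustained_rest`` — 10 s of rest starting 40 s after the end of the same
                     qualifying bouts as ``initial_rest``.

A single bout may emit several window classes; the offset and initial-rest
windows of one bout overlap by construction and both are kept.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["STATES", "binarize_locomotion", "segment_states", "segment_pipeline"]

STATES = ("onset", "locomotion", "offset", "initial_rest", "sustained_rest")

WINDOW_S = 10.0

# duration rules (seconds)
_ONSET_PRE_REST = 5.0
_ONSET_MIN_BOUT = 5.0
_LOCO_MIN_BOUT = 20.0
_LOCO_PRE_REST = 60.0
_OFFSET_MIN_BOUT = 20.0
_OFFSET_POST_REST = 10.0
_IREST_MIN_BOUT = 5.0
_IREST_POST_REST = 60.0
_SREST_DELAY = 40.0


def _run_lengths(flags: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean trace as (start, stop, value) spans."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    change = np.flatnonzero(np.diff(flags)) + 1
    bounds = np.concatenate(([0], change, [flags.size]))
    return [(int(a), int(b), bool(flags[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def binarize_locomotion(
    velocity: np.ndarray,
    fs: float,
    threshold: float = 0.25,
    min_bout_s: float = 1.0,
    min_gap_s: float = 1.0,
) -> np.ndarray:
    """Per-sample run flag ``|v| > threshold`` with short-event smoothing.

    Rest gaps shorter than ``min_gap_s`` inside running are filled first,
    then run bouts shorter than ``min_bout_s`` are suppressed, so an
    isolated velocity spike does not create a bout.
    """
    v = np.asarray(velocity, dtype=float).ravel()
    flags = np.abs(v) > threshold
    min_gap = int(round(min_gap_s * fs))
    for a, b, val in _run_lengths(flags):
        if not val and b - a < min_gap and a > 0 and b < flags.size:
            flags[a:b] = True
    min_bout = int(round(min_bout_s * fs))
    for a, b, val in _run_lengths(flags):
        if val and b - a < min_bout:
            flags[a:b] = False
    return flags


def segment_states(run_flags: np.ndarray, fs: float) -> pd.DataFrame:
    """Extract the five classes of 10-s windows from a binarized trace.

    Returns a table with columns ``state, start_s, end_s, bout_id`` sorted
    by start time; every emitted window satisfies its class's duration
    preconditions and lies fully inside the trace.
    """
    flags = np.asarray(run_flags, dtype=bool)
    n = flags.size
    if n / fs < WINDOW_S:
        warnings.warn("trace shorter than one analysis window; empty table")
        return pd.DataFrame(columns=["state", "start_s", "end_s", "bout_id"])

    spans = _run_lengths(flags)
    rows: list[tuple[str, float, float, int]] = []
    bout_id = -1
    for k, (a, b, val) in enumerate(spans):
        if not val:
            continue
        bout_id += 1
        t0, t1 = a / fs, b / fs
        bout = t1 - t0
        # rest flanks; the trace edge bounds how much rest can be claimed
        pre = t0 - (spans[k - 1][0] / fs) if k > 0 else 0.0
        post = (spans[k + 1][1] / fs) - t1 if k < len(spans) - 1 else 0.0

        def emit(state: str, start: float) -> None:
            end = start + WINDOW_S
            if start >= 0 and end <= n / fs:
                rows.append((state, start, end, bout_id))

        if pre >= _ONSET_PRE_REST and bout >= _ONSET_MIN_BOUT:
            emit("onset", t0 - 5.0)
        if bout >= _LOCO_MIN_BOUT and pre >= _LOCO_PRE_REST:
            mid = round((t0 + t1) / 2.0 * fs) / fs  # snap to sample grid
            emit("locomotion", mid - 5.0)
        if bout >= _OFFSET_MIN_BOUT and post >= _OFFSET_POST_REST:
            emit("offset", t1 - 5.0)
        if bout >= _IREST_MIN_BOUT and post >= _IREST_POST_REST:
            emit("initial_rest", t1)
            emit("sustained_rest", t1 + _SREST_DELAY)

    df = pd.DataFrame(rows, columns=["state", "start_s", "end_s", "bout_id"])
    return df.sort_values("start_s", kind="stable").reset_index(drop=True)


def segment_pipeline(
    velocity: np.ndarray,
    fs: float,
    threshold: float = 0.25,
    min_bout_s: float = 1.0,
    min_gap_s: float = 1.0,
) -> pd.DataFrame:
    """Velocity trace -> labeled 10-s behavioral windows."""
    flags = binarize_locomotion(velocity, fs, threshold, min_bout_s, min_gap_s)
    return segment_states(flags, fs)
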