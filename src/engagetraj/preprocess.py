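"""From raw log-in events to the smoothed trajectories the clustering uses.

The engagement measure is day-level and binary: did the participant open
the app at least once on day ``d`` (0-based, day 0 = randomization), for
182 days.  Participants who never logged in are excluded from the analysis
set, mirroring the at-least-one-log-in cohort definition.  Binary series
are then presmoothed with a trailing 7-day moving average (including the
current day, window shrinking at the series start), which turns each
series into a dense functional datum on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from engagetraj.synth import N_DAYS, N_WEEKS, ParticipantRecord


@dataclass
class DailyEngagementMatrix:
    """n x 182 binary log-in indicators, one row per retained participant."""

    participant_ids: list[str]
    values: np.ndarray
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != N_DAYS:
            raise ValueError(f"values must be n x {N_DAYS}")
        if len(self.participant_ids) != self.values.shape[0]:
            raise ValueError("participant_ids must align with rows")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SmoothedTrajectoryMatrix:
    """Trailing-window mean of the binary matrix; entries in [0, 1]."""

    participant_ids: list[str]
    values: np.ndarray
    window_length: int = 7

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_DAYS:
            raise ValueError(f"values must be n x {N_DAYS}")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("smoothed values must lie in [0, 1]")


def matrix_from_records(
    records: Sequence[ParticipantRecord], drop_zero: bool = True
) -> DailyEngagementMatrix:
    """Stack synthetic participants into a DailyEngagementMatrix,
    excluding zero-log-in participants by default (analysis-set rule)."""
    ids = [r.id for r in records]
    values = np.stack([r.daily_logins for r in records]) if records else (
        np.zeros((0, N_DAYS), dtype=np.int8)
    )
    if not drop_zero:
        return DailyEngagementMatrix(ids, values)
    keep = values.sum(axis=1) > 0
    excluded = [pid for pid, k in zip(ids, keep) if not k]
    return DailyEngagementMatrix(
        [pid for pid, k in zip(ids, keep) if k], values[keep], excluded
    )


def _day_offsets(
    events: pd.DataFrame, anchors: Mapping[str, object] | None
) -> pd.Series:
    if "day_index" in events.columns:
        return events["day_index"].astype(int)
    if "timestamp" not in events.columns:
        raise ValueError("events must have a 'day_index' or 'timestamp' column")
    if anchors is None:
        raise ValueError("timestamp events require per-participant anchor dates")
    ts = pd.to_datetime(events["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unparseable timestamp at events row {row}")
    anchor_dates = events["participant_id"].map(
        {pid: pd.Timestamp(a).normalize() for pid, a in anchors.items()}
    )
    return (ts.dt.normalize() - anchor_dates).dt.days


def binarize_events(
    events: pd.DataFrame,
    participants: Sequence[str] | Mapping[str, object],
) -> DailyEngagementMatrix:
    """Build the day-level binary matrix from a long event table.

    ``participants`` is either an ordered sequence of participant ids
    (events carry a ``day_index`` column) or a mapping id -> anchor date
    (events carry parseable ``timestamp``s; the day offset is the calendar
    difference from the participant's anchor).  Entry (i, d) is 1 iff
    participant i has at least one event on day d; offsets outside
    [0, 182) are ignored.  Participants with no in-window events are
    excluded and listed in ``excluded_ids``.
    """
    if isinstance(participants, Mapping):
        ids = list(participants.keys())
        anchors: Mapping[str, object] | None = participants
    else:
        ids = list(participants)
        anchors = None
    index = {pid: i for i, pid in enumerate(ids)}

    unknown = set(events["participant_id"]) - set(index)
    if unknown:
        raise ValueError(f"events reference unknown participants: {sorted(unknown)[:5]}")

    values = np.zeros((len(ids), N_DAYS), dtype=np.int8)
    offsets = _day_offsets(events, anchors).to_numpy()
    rows = events["participant_id"].map(index).to_numpy()
    in_window = (offsets >= 0) & (offsets < N_DAYS)
    values[rows[in_window], offsets[in_window]] = 1

    keep = values.sum(axis=1) > 0
    excluded = [pid for pid, k in zip(ids, keep) if not k]
    return DailyEngagementMatrix(
        [pid for pid, k in zip(ids, keep) if k], values[keep], excluded
    )


def read_wide_matrix(path: str | Path) -> DailyEngagementMatrix:
    """Read a prebuilt wide CSV (participant_id, d0..d181)."""
    df = pd.read_csv(path, comment="#")
    cols = [f"d{i}" for i in range(N_DAYS)]
    return DailyEngagementMatrix(df["participant_id"].astype(str).tolist(),
                                 df[cols].to_numpy())


def write_smoothed_csv(smoothed: SmoothedTrajectoryMatrix, path: str | Path) -> None:
    """Write a smoothed matrix as CSV (participant_id, d0..d181), same row order."""
    df = pd.DataFrame(smoothed.values, columns=[f"d{i}" for i in range(N_DAYS)])
    df.insert(0, "participant_id", smoothed.participant_ids)
    df.to_csv(path, index=False)


def presmooth(matrix: DailyEngagementMatrix, window: int = 7) -> SmoothedTrajectoryMatrix:
    """Trailing moving average over ``window`` days including the current
    day; the window shrinks at the series start (mean over days 0..t for
    t < window-1) so early values are unbiased rather than attenuated."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = matrix.values.astype(float)
    cs = np.cumsum(x, axis=1)
    t = np.arange(N_DAYS)
    totals = cs.copy()
    totals[:, window:] = cs[:, window:] - cs[:, :-window]
    lengths = np.minimum(t + 1, window)
    return SmoothedTrajectoryMatrix(
        list(matrix.participant_ids), totals / lengths, window
    )


def weekly_login_sums(values: np.ndarray) -> np.ndarray:
    """Per-participant weekly log-in day counts: n x 26."""
    return np.asarray(values).reshape(len(values), N_WEEKS, 7).sum(axis=2)


def weekly_login_summary(
    matrix: DailyEngagementMatrix, labels: Sequence[int]
) -> pd.DataFrame:
    """Per-group mean weekly log-in days (rows: group, columns: week1..26)."""
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n:
        raise ValueError("labels must align with matrix rows")
    weekly = weekly_login_sums(matrix.values)
    out = {}
    for g in np.unique(labels):
        out[g] = weekly[labels == g].mean(axis=0)
    df = pd.DataFrame.from_dict(out, orient="index",
                                columns=[f"week{w}" for w in range(1, N_WEEKS + 1)])
    df.index.name = "group"
    return df
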