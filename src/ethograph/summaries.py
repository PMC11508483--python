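"""Summary tables behind the distinct-behavior chart, the behavioral
timeline and the cumulative temporal-occurrences chart."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .events import BehaviorBout

logger = logging.getLogger(__name__)

GroupBy = Literal["behavior", "category"]


def _label(bout: BehaviorBout, group_by: GroupBy) -> str:
    if group_by == "behavior":
        return bout.behavior
    if group_by == "category":
        return bout.category
    raise ValueError(f"group_by must be 'behavior' or 'category', got {group_by!r}")


def behavior_counts(
    bouts: Sequence[BehaviorBout], group_by: GroupBy = "behavior"
) -> pd.DataFrame:
    """Count bouts and total durations per behavior (or category).

    Returns a DataFrame indexed by label with columns ``count``,
    ``total_duration``, ``relative_count`` and ``relative_duration``; the
    relative columns are the absolute ones normalized by their column sum
    (this is the data behind both the bar chart and the relative pie
    chart). When all bouts are point events the duration sum is zero and
    ``relative_duration`` is set to 0. An empty bout list yields an empty
    table.
    """
    _label_check(group_by)
    cols = ["count", "total_duration", "relative_count", "relative_duration"]
    if not bouts:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "label": [_label(b, group_by) for b in bouts],
            "duration": [b.duration for b in bouts],
        }
    )
    agg = df.groupby("label")["duration"].agg(count="size", total_duration="sum")
    agg = agg.sort_index()
    agg["relative_count"] = agg["count"] / agg["count"].sum()
    dur_sum = agg["total_duration"].sum()
    agg["relative_duration"] = agg["total_duration"] / dur_sum if dur_sum > 0 else 0.0
    agg.index.name = group_by
    return agg[cols]


def _label_check(group_by: str) -> None:
    if group_by not in ("behavior", "category"):
        raise ValueError(f"group_by must be 'behavior' or 'category', got {group_by!r}")


@dataclass
class IntervalTracks:
    """Per-subject timeline: one track of [start, stop] intervals per label."""

    subject: str
    tracks: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


def timeline(
    bouts: Sequence[BehaviorBout], subject: str, group_by: GroupBy = "behavior"
) -> IntervalTracks:
    """Collect the intervals of one subject's bouts, grouped by label.

    Every bout of the subject contributes exactly one interval to its
    track; point events give degenerate ``[t, t]`` intervals. An unknown
    subject yields empty tracks with a logged warning.
    """
    _label_check(group_by)
    own = [b for b in bouts if b.subject == subject]
    if not own:
        logger.warning("subject %r has no bouts; timeline is empty", subject)
        return IntervalTracks(subject=subject)
    tracks: dict[str, list[tuple[float, float]]] = {}
    for b in sorted(own, key=lambda b: (b.start, b.row_index)):
        tracks.setdefault(_label(b, group_by), []).append((b.start, b.stop))
    return IntervalTracks(subject=subject, tracks=tracks)


@dataclass
class StepSeries:
    """A cumulative-count step series for one subject (or subject, label).

    ``points`` are (time, cumulative count) pairs with strictly increasing
    times and nondecreasing counts; the final count equals the key's total
    number of bouts.
    """

    key: tuple[str, ...]
    points: list[tuple[float, int]]

    @property
    def total(self) -> int:
        return self.points[-1][1] if self.points else 0


def cumulative_occurrences(
    bouts: Sequence[BehaviorBout],
    mode: Literal["per_subject", "per_subject_behavior"] = "per_subject",
    group_by: GroupBy = "behavior",
) -> list[StepSeries]:
    """Cumulative bout counts over time, one series per subject
    (or per subject x behavior/category in the alternative mode).

    A bout increments its series at its start time; bouts sharing a start
    time collapse into a single step of the combined height.
    """
    _label_check(group_by)
    if mode not in ("per_subject", "per_subject_behavior"):
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[tuple[str, ...], list[float]] = {}
    for b in bouts:
        key = (b.subject,) if mode == "per_subject" else (b.subject, _label(b, group_by))
        groups.setdefault(key, []).append(b.start)
    series = []
    for key in sorted(groups):
        starts = sorted(groups[key])
        points: list[tuple[float, int]] = []
        for t in starts:
            if points and points[-1][0] == t:
                points[-1] = (t, points[-1][1] + 1)
            else:
                points.append((t, (points[-1][1] if points else 0) + 1))
        series.append(StepSeries(key=key, points=points))
    return series


def count_table_csv(table: pd.DataFrame) -> str:
    """Serialize a count table (or any per-label table) as CSV text."""
    return table.to_csv()


def step_series_csv(series: Sequence[StepSeries]) -> str:
    """Serialize step series as long-format CSV (key, time, cumulative count)."""
    rows = [
        {"key": "|".join(s.key), "time": t, "cumulative_count": c}
        for s in series
        for t, c in s.points
    ]
    return pd.DataFrame(rows, columns=["key", "time", "cumulative_count"]).to_csv(
        index=False
    )
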