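"""Cry-sequence segmentation and cohort summaries.

A *cry sequence* is a period during which an infant cries continuously or
intermittently. On the 5-s epoch grid it is defined by hysteresis:

* start criterion — at least ``start_min_cry`` cry epochs within any
  sliding window of ``start_window`` epochs (defaults 6 within 12, i.e.
  six 5-s cry epochs within one minute);
* stop criterion — a run of at least ``stop_gap`` consecutive non-cry
  epochs (default 60, i.e. five minutes of silence).

A sequence starts at the first cry epoch of the earliest triggering
window and ends at the last cry epoch before the terminating silence, so
internal pauses shorter than the stop gap are bridged but unbounded
trailing silence is never counted. Sub-threshold crying between sequences
belongs to no sequence.

The cohort summary reproduces the shape of a per-subject validation
table: annotated vs predicted sequence counts and durations, their
absolute differences, and per-group medians of total cry duration.
All quantiles are type-7 (linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPOCH_MINUTES = 5.0 / 60.0

DEFAULT_START_MIN_CRY = 6
DEFAULT_START_WINDOW = 12
DEFAULT_STOP_GAP = 60


@dataclass
class EpochLabelSeries:
    """Ordered binary cry labels (1 = cry) on the 5-s epoch grid."""

    labels: np.ndarray
    subject: str | None = None
    group: str | None = None
    origin: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.size and not np.isin(labels, (0, 1)).all():
            raise ValueError("epoch labels must be binary (0/1)")
        self.labels = labels

    def __len__(self) -> int:
        return self.labels.size

    @property
    def cry_epochs(self) -> int:
        return int(self.labels.sum())

    @property
    def cry_minutes(self) -> float:
        return self.cry_epochs * EPOCH_MINUTES


@dataclass(frozen=True)
class CrySequence:
    start_epoch: int
    end_epoch: int  # inclusive
    contained_cry_epochs: int

    def __post_init__(self) -> None:
        if self.end_epoch < self.start_epoch:
            raise ValueError("sequence end before start")

    @property
    def duration_min(self) -> float:
        return (self.end_epoch - self.start_epoch + 1) * EPOCH_MINUTES


@dataclass
class SequenceSummary:
    subject: str | None
    sequences: list[CrySequence]

    @property
    def count(self) -> int:
        return len(self.sequences)

    @property
    def total_duration_min(self) -> float:
        return sum(s.duration_min for s in self.sequences)

    @property
    def total_cry_epochs(self) -> int:
        return sum(s.contained_cry_epochs for s in self.sequences)


@dataclass
class SubjectRecord:
    """Per-subject row of the cohort table (annotated vs predicted)."""

    subject: str | None
    annotated_count: int
    predicted_count: int
    annotated_duration_min: float
    predicted_duration_min: float
    annotated_cry_epochs: int
    group: str | None = None

    @property
    def abs_count_diff(self) -> int:
        return abs(self.annotated_count - self.predicted_count)

    @property
    def abs_duration_diff_min(self) -> float:
        return abs(self.annotated_duration_min - self.predicted_duration_min)


@dataclass
class TimelineComparison:
    annotated: SequenceSummary
    predicted: SequenceSummary
    annotated_cry_epochs: int
    subject: str | None = None
    group: str | None = None

    @property
    def abs_count_diff(self) -> int:
        return abs(self.annotated.count - self.predicted.count)

    @property
    def abs_duration_diff_min(self) -> float:
        return abs(self.annotated.total_duration_min - self.predicted.total_duration_min)

    @property
    def record(self) -> SubjectRecord:
        return SubjectRecord(
            subject=self.subject,
            annotated_count=self.annotated.count,
            predicted_count=self.predicted.count,
            annotated_duration_min=self.annotated.total_duration_min,
            predicted_duration_min=self.predicted.total_duration_min,
            annotated_cry_epochs=self.annotated_cry_epochs,
            group=self.group,
        )


def _as_labels(series) -> np.ndarray:
    labels = np.asarray(getattr(series, "labels", series), dtype=np.int64)
    if labels.size and not np.isin(labels, (0, 1)).all():
        raise ValueError("epoch labels must be binary (0/1)")
    return labels


def detect_sequences(
    series,
    start_min_cry: int = DEFAULT_START_MIN_CRY,
    start_window: int = DEFAULT_START_WINDOW,
    stop_gap: int = DEFAULT_STOP_GAP,
) -> list[CrySequence]:
    """Segment a binary epoch series into cry sequences.

    Scans left to right. A sequence opens at the first cry epoch of the
    earliest ``start_window``-epoch window (windows at the series tail are
    truncated) containing at least ``start_min_cry`` cry epochs, and
    closes at the last cry epoch preceding the first run of at least
    ``stop_gap`` consecutive non-cry epochs (or the end of the series).
    Scanning resumes after the closed sequence, so sequences never
    overlap.
    """
    if start_min_cry <= 0 or start_window <= 0 or stop_gap <= 0:
        raise ValueError("sequence parameters must be positive")
    if start_min_cry > start_window:
        raise ValueError("start_min_cry cannot exceed start_window")
    # plain-python scan: the function is called per subject on short
    # series, where list arithmetic beats array dispatch overhead
    labels = getattr(series, "labels", series)
    if isinstance(labels, np.ndarray):
        if labels.size and not np.isin(labels, (0, 1)).all():
            raise ValueError("epoch labels must be binary (0/1)")
        labels = labels.astype(np.int64).tolist()
    else:
        labels = list(labels)
        if any(v not in (0, 1) for v in labels):
            raise ValueError("epoch labels must be binary (0/1)")
    n = len(labels)
    if n == 0 or sum(labels) < start_min_cry:
        return []

    # prefix sums -> cry count of the (tail-truncated) window at each start
    csum = [0] * (n + 1)
    for i, v in enumerate(labels):
        csum[i + 1] = csum[i] + v
    # length of the zero run starting at each position (0 on cry epochs)
    zero_run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        zero_run[i] = 0 if labels[i] else zero_run[i + 1] + 1

    sequences: list[CrySequence] = []
    pos = 0
    while pos < n:
        w = pos
        while w < n:
            win_end = w + start_window if w + start_window < n else n
            if csum[win_end] - csum[w] >= start_min_cry:
                break
            w += 1
        else:
            break
        if w >= n:
            break
        # sequence opens at the first cry epoch of the triggering window
        start = w
        while not labels[start]:
            start += 1
        # close at the last cry epoch before the first >= stop_gap zero run
        end = start
        k = start
        while k < n:
            if labels[k]:
                end = k
                k += 1
            else:
                if zero_run[k] >= stop_gap:
                    break
                k += zero_run[k]
        sequences.append(
            CrySequence(
                start_epoch=start,
                end_epoch=end,
                contained_cry_epochs=csum[end + 1] - csum[start],
            )
        )
        pos = end + 1
    return sequences


def summarize(series, subject: str | None = None, **params) -> SequenceSummary:
    return SequenceSummary(
        subject=subject if subject is not None else getattr(series, "subject", None),
        sequences=detect_sequences(series, **params),
    )


def compare_timelines(annotated, predicted, **params) -> TimelineComparison:
    """Detect sequences on both timelines and assemble the comparison."""
    a = _as_labels(annotated)
    p = _as_labels(predicted)
    if a.size != p.size:
        raise ValueError(f"timeline lengths differ: {a.size} vs {p.size}")
    subject = getattr(annotated, "subject", None)
    group = getattr(annotated, "group", None)
    return TimelineComparison(
        annotated=SequenceSummary(subject, detect_sequences(a, **params)),
        predicted=SequenceSummary(subject, detect_sequences(p, **params)),
        annotated_cry_epochs=int(a.sum()),
        subject=subject,
        group=group,
    )


def _median_iqr(values) -> dict[str, float]:
    arr = np.asarray(values, dtype=np.float64)
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])  # type-7
    return {"median": float(q50), "iqr_low": float(q25), "iqr_high": float(q75)}


def summarize_cohort(comparisons) -> dict:
    """Cohort-level statistics over per-subject timeline comparisons.

    Accepts TimelineComparison objects or bare SubjectRecord rows.
    Duration-difference statistics are restricted to subjects with at
    least one annotated sequence (a subject who never cried contributes
    no duration mismatch).
    """
    records = [c.record if isinstance(c, TimelineComparison) else c for c in comparisons]
    if not records:
        raise ValueError("summarize_cohort requires at least one subject")
    counts = [r.annotated_count for r in records]
    with_seq = [r for r in records if r.annotated_count >= 1]
    out = {
        "n_subjects": len(records),
        "total_annotated_sequences": int(sum(counts)),
        "annotated_sequence_count": _median_iqr(counts),
        "abs_count_diff": _median_iqr([r.abs_count_diff for r in records]),
    }
    if with_seq:
        out["abs_duration_diff_min"] = _median_iqr(
            [r.abs_duration_diff_min for r in with_seq]
        )
    groups = sorted({r.group for r in records if r.group is not None})
    by_group = {}
    for g in groups:
        durations = [
            r.annotated_cry_epochs * EPOCH_MINUTES for r in records if r.group == g
        ]
        by_group[g] = _median_iqr(durations)
    if by_group:
        out["cry_duration_min_by_group"] = by_group
    return out
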