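import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crydetect.metrics import format_percent
from crydetect.sequences import (
    EpochLabelSeries,
    SubjectRecord,
    compare_timelines,
    detect_sequences,
    summarize_cohort,
)
from conftest import brute_force_sequences


def blocks_to_labels(length, blocks):
    labels = np.zeros(length, dtype=int)
    for start, stop in blocks:  # inclusive bounds
        labels[start : stop + 1] = 1
    return labels


def test_all_zero_series_has_no_sequences():
    assert detect_sequences(np.zeros(500, int)) == []
    assert detect_sequences([]) == []


def test_minimal_start_criterion():
    """Six consecutive cry epochs in silence: one 0.5-min sequence."""
    labels = blocks_to_labels(200, [(100, 105)])
    seqs = detect_sequences(labels)
    assert len(seqs) == 1
    assert (seqs[0].start_epoch, seqs[0].end_epoch) == (100, 105)
    assert seqs[0].duration_min == pytest.approx(0.5)
    assert seqs[0].contained_cry_epochs == 6


def test_subthreshold_crying_never_opens():
    """5 cries then 8 silences, repeated: never 6 within any 12-epoch window."""
    labels = np.tile([1] * 5 + [0] * 8, 30)
    assert detect_sequences(labels) == []


def test_internal_pauses_are_bridged_but_trailing_silence_is_not():
    # two cry bursts 30 epochs apart (< 60): one sequence ending at last cry
    labels = blocks_to_labels(400, [(10, 20), (50, 60)])
    seqs = detect_sequences(labels)
    assert len(seqs) == 1
    assert (seqs[0].start_epoch, seqs[0].end_epoch) == (10, 60)
    # same bursts 100 epochs apart (>= 60): two sequences
    labels = blocks_to_labels(400, [(10, 20), (120, 130)])
    assert [(s.start_epoch, s.end_epoch) for s in detect_sequences(labels)] == [
        (10, 20), (120, 130)
    ]


def test_sequence_bounds_are_cry_epochs():
    rng = np.random.default_rng(5)
    for _ in range(50):
        labels = (rng.random(500) < 0.1).astype(int)
        for s in detect_sequences(labels):
            assert labels[s.start_epoch] == 1 and labels[s.end_epoch] == 1


def test_matches_brute_force_on_random_series():
    rng = np.random.default_rng(12)
    for _ in range(200):
        labels = (rng.random(720) < rng.uniform(0.02, 0.3)).astype(int)
        got = [(s.start_epoch, s.end_epoch, s.contained_cry_epochs)
               for s in detect_sequences(labels)]
        assert got == brute_force_sequences(labels, 6, 12, 60)


def test_matches_brute_force_exhaustive_small():
    """All binary series up to length 12 with scaled parameters."""
    import itertools

    for n in range(1, 13):
        for bits in itertools.product((0, 1), repeat=n):
            got = [(s.start_epoch, s.end_epoch, s.contained_cry_epochs)
                   for s in detect_sequences(list(bits), 2, 4, 5)]
            assert got == brute_force_sequences(bits, 2, 4, 5), bits


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=120), st.data())
def test_adding_cry_epochs_never_shrinks_total_duration(labels, data):
    """Monotonicity under fixed parameters (scaled: 2 within 4, stop 5)."""
    base = list(labels)
    idx = data.draw(st.integers(0, len(base) - 1))
    more = list(base)
    more[idx] = 1
    dur = lambda lab: sum(s.duration_min for s in detect_sequences(lab, 2, 4, 5))
    assert dur(more) >= dur(base)


def test_parameter_validation():
    with pytest.raises(ValueError):
        detect_sequences([0, 1], start_min_cry=0)
    with pytest.raises(ValueError):
        detect_sequences([0, 1], start_min_cry=5, start_window=4)
    with pytest.raises(ValueError):
        detect_sequences([0, 2, 1])


def test_compare_identical_timelines():
    labels = blocks_to_labels(300, [(10, 40)])
    cmp = compare_timelines(EpochLabelSeries(labels), EpochLabelSeries(labels))
    assert cmp.abs_count_diff == 0
    assert cmp.abs_duration_diff_min == 0.0


def test_sparse_flips_outside_sequences_leave_counts_unchanged():
    rng = np.random.default_rng(21)
    ann = blocks_to_labels(1000, [(100, 180), (400, 470)])
    pred = ann.copy()
    # flip isolated epochs at least one stop-gap away from any cry, spaced
    # so no 12-epoch window ever holds 6 cries: nothing can open or bridge
    flips = np.arange(540, 1000, 12)
    assert np.all(ann[flips] == 0)
    pred[flips] = 1
    cmp = compare_timelines(EpochLabelSeries(ann), EpochLabelSeries(pred))
    assert cmp.abs_count_diff == 0


def test_subject1_shaped_timeline_deltas():
    """3 annotated sequences / 37 min vs 5 predicted / 59 min -> deltas 2, 22."""
    n = 2000
    ann = blocks_to_labels(n, [(0, 119), (200, 343), (420, 599)])  # 444 epochs
    pred = blocks_to_labels(
        n, [(0, 119), (200, 343), (420, 599), (700, 831), (900, 1031)]
    )  # 708 epochs
    cmp = compare_timelines(EpochLabelSeries(ann), EpochLabelSeries(pred))
    assert cmp.annotated.count == 3
    assert cmp.predicted.count == 5
    assert cmp.annotated.total_duration_min == pytest.approx(37.0)
    assert cmp.predicted.total_duration_min == pytest.approx(59.0)
    assert cmp.abs_count_diff == 2
    assert cmp.abs_duration_diff_min == pytest.approx(22.0)


# Per-subject validation-cohort shape: (group, annotated count, predicted
# count, annotated dur min, predicted dur min, annotated cry epochs)
COHORT_TABLE = [
    ("hospital", 3, 5, 37, 59, 145),
    ("hospital", 3, 3, 19, 21, 65),
    ("hospital", 1, 1, 5, 6, 12),
    ("hospital", 3, 3, 17, 25, 52),
    ("hospital", 1, 1, 7, 8, 17),
    ("hospital", 7, 7, 117, 122, 721),
    ("hospital", 1, 1, 6, 8, 26),
    ("hospital", 7, 8, 55, 72, 200),
    ("hospital", 3, 3, 18.5, 26, 70),
    ("hospital", 3, 3, 22, 36, 99),
    ("hospital", 6, 7, 64, 80, 320),
    ("home", 1, 1, 2.8, 2.4, 38),
    ("home", 0, 0, 0, 0, 7),
    ("home", 0, 0, 0, 0, 25),
    ("home", 0, 0, 0, 0, 8),
]


def cohort_records():
    return [
        SubjectRecord(
            subject=str(i + 1), group=g, annotated_count=ac, predicted_count=pc,
            annotated_duration_min=ad, predicted_duration_min=pd,
            annotated_cry_epochs=ce,
        )
        for i, (g, ac, pc, ad, pd, ce) in enumerate(COHORT_TABLE)
    ]


def test_cohort_summary_reproduces_published_statistics():
    out = summarize_cohort(cohort_records())
    assert out["total_annotated_sequences"] == 39
    assert out["annotated_sequence_count"]["median"] == 3
    assert out["annotated_sequence_count"]["iqr_low"] == 1
    assert out["annotated_sequence_count"]["iqr_high"] == 3
    by_group = out["cry_duration_min_by_group"]
    assert round(by_group["hospital"]["median"], 1) == 5.8
    assert round(by_group["home"]["median"], 1) == 1.4


def test_cohort_single_subject():
    out = summarize_cohort(cohort_records()[:1])
    assert out["annotated_sequence_count"]["median"] == 3
    assert out["annotated_sequence_count"]["iqr_high"] == out[
        "annotated_sequence_count"
    ]["iqr_low"]
    with pytest.raises(ValueError):
        summarize_cohort([])
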