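import numpy as np
import pytest

from crydetect.classify import LabeledDataset, grid_search_cv, select_final_model
from crydetect.pipeline import extract_clip_features, make_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Small labeled clip corpus with its feature matrix (fast, shared)."""
    clips, labels = make_corpus(n_cry=30, n_noncry=40, seed=11)
    matrix = extract_clip_features(clips)
    return clips, labels, matrix


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A quick model trained on the small corpus (logistic regression only)."""
    _, labels, matrix = small_corpus
    data = LabeledDataset(matrix=matrix, labels=labels)
    result = grid_search_cv(data, "logistic_regression", k=5, seed=11)
    return select_final_model([result], data, seed=11)


def brute_force_sequences(labels, start_min_cry, start_window, stop_gap):
    """Independent re-implementation of the cry-sequence criteria.

    Naive nested scan: find the earliest window with enough cry epochs,
    open at its first cry, walk forward counting consecutive silence to
    close, repeat after the close. Used as the oracle for
    detect_sequences.
    """
    labels = list(labels)
    n = len(labels)
    seqs = []
    i = 0
    while i < n:
        opened = None
        for w in range(i, n):
            if sum(labels[w : w + start_window]) >= start_min_cry:
                for j in range(w, min(w + start_window, n)):
                    if labels[j]:
                        opened = j
                        break
                break
        if opened is None:
            break
        run = 0
        end = opened
        close = None
        for k in range(opened, n):
            if labels[k]:
                end = k
                run = 0
            else:
                run += 1
                if run >= stop_gap:
                    close = end
                    break
        if close is None:
            close = end
        seqs.append((opened, close, sum(labels[opened : close + 1])))
        i = close + 1
    return seqs
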