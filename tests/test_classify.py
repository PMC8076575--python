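import numpy as np
import pandas as pd
import pytest

from crydetect.classify import (
    FAMILIES,
    LabeledDataset,
    TrainedModel,
    grid_search_cv,
    make_estimator,
    pick_best,
    predict_epochs,
    select_final_model,
)


def separable_dataset(n=200, seed=0):
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    X = np.vstack(
        [
            rng.normal([3.0, 3.0], 0.3, size=(n_pos, 2)),
            rng.normal([-3.0, -3.0], 0.3, size=(n - n_pos, 2)),
        ]
    )
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    return LabeledDataset(matrix=pd.DataFrame(X, columns=["a", "b"]), labels=y)


SMALL_GRIDS = {
    "random_forest": [{"n_estimators": 30, "max_depth": None, "min_samples_leaf": 1}],
    "logistic_regression": [{"C": 1.0}],
    "naive_bayes": [{"var_smoothing": 1e-9}],
}


@pytest.mark.parametrize("family", FAMILIES)
def test_separable_data_reaches_full_sensitivity(family):
    data = separable_dataset(seed=3)
    result = grid_search_cv(data, family, k=5, seed=3, grid=SMALL_GRIDS[family])
    assert result.mean("sensitivity") == 1.0
    assert result.mean("mcc") == 1.0
    assert len(result.fold_metrics) == 5


def test_shuffled_labels_give_chance_level_mcc():
    """Permutation null: mean CV MCC near 0 over 10 label shuffles."""
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.standard_normal((400, 4)), columns=list("abcd"))
    mccs = []
    for i in range(10):
        y = np.array([0, 1] * 200)
        rng.shuffle(y)
        data = LabeledDataset(matrix=X, labels=y)
        r = grid_search_cv(
            data, "naive_bayes", k=5, seed=i, grid=SMALL_GRIDS["naive_bayes"]
        )
        mccs.append(r.mean("mcc"))
    assert abs(float(np.mean(mccs))) <= 0.15


def test_sensitivity_first_tie_break():
    """Equal sensitivity -> higher MCC wins; full tie -> grid order wins."""
    cands = [({"id": 1}, 0.9, 0.5), ({"id": 2}, 0.9, 0.7), ({"id": 3}, 0.8, 0.99)]
    assert pick_best(cands) == {"id": 2}
    assert pick_best([({"id": 1}, 0.9, 0.5), ({"id": 2}, 0.9, 0.5)]) == {"id": 1}
    assert pick_best([({"id": 1}, 0.5, 0.9), ({"id": 2}, 0.6, 0.1)]) == {"id": 2}
    with pytest.raises(ValueError):
        pick_best([])


def test_grid_search_contract_errors():
    data = separable_dataset()
    single = LabeledDataset(
        matrix=data.matrix, labels=np.ones(len(data.matrix), dtype=int)
    )
    with pytest.raises(ValueError, match="both classes"):
        grid_search_cv(single, "random_forest")
    with pytest.raises(ValueError, match="folds exceed"):
        tiny = LabeledDataset(
            matrix=data.matrix.iloc[:6], labels=np.array([1, 1, 1, 0, 0, 0])
        )
        grid_search_cv(tiny, "naive_bayes", k=5)
    with pytest.raises(ValueError, match="unknown model family"):
        grid_search_cv(data, "svm")


def test_final_model_selection_and_refit():
    data = separable_dataset(seed=5)
    results = [
        grid_search_cv(data, fam, k=5, seed=5, grid=SMALL_GRIDS[fam])
        for fam in FAMILIES
    ]
    model = select_final_model(results, data, seed=5)
    best_mcc = max(r.mean("mcc") for r in results)
    chosen = next(r for r in results if r.family == model.family)
    assert chosen.mean("mcc") == best_mcc
    # refit predicts its own training set at least as well as the CV folds
    series, proba = predict_epochs(model, data.matrix)
    from crydetect.metrics import compute_metrics, confusion

    refit_mcc = compute_metrics(confusion(data.labels, series.labels)).mcc
    assert refit_mcc >= max(m.mcc for m in chosen.fold_metrics) - 0.05
    with pytest.raises(ValueError):
        select_final_model([], data)


def test_model_serialization_round_trip(tmp_path):
    data = separable_dataset(seed=7)
    result = grid_search_cv(
        data, "random_forest", k=5, seed=7, grid=SMALL_GRIDS["random_forest"]
    )
    model = select_final_model([result], data, seed=7)
    holdout = separable_dataset(n=100, seed=99).matrix
    _, proba_before = predict_epochs(model, holdout)
    path = tmp_path / "model.bin"
    model.save(path)
    reloaded = TrainedModel.load(path)
    _, proba_after = predict_epochs(reloaded, holdout)
    assert np.array_equal(proba_before, proba_after)


def test_determinism_given_seed():
    data = separable_dataset(seed=2)
    a = grid_search_cv(data, "random_forest", k=5, seed=9,
                       grid=SMALL_GRIDS["random_forest"])
    b = grid_search_cv(data, "random_forest", k=5, seed=9,
                       grid=SMALL_GRIDS["random_forest"])
    assert a.params == b.params
    assert [m.as_dict() for m in a.fold_metrics] == [
        m.as_dict() for m in b.fold_metrics
    ]


class _FixedProba:
    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([1 - np.full(len(X), self.p), np.full(len(X), self.p)])


def test_threshold_boundary_labels_cry():
    """Probability exactly at the threshold is labeled cry (>= convention)."""
    model = TrainedModel(
        family="naive_bayes", params={}, estimator=_FixedProba(0.5),
        feature_names=("a",), threshold=0.5,
    )
    matrix = pd.DataFrame({"a": [0.0, 1.0]})
    series, proba = predict_epochs(model, matrix)
    assert np.all(series.labels == 1)
    assert np.all(proba == 0.5)


def test_empty_matrix_and_registry_mismatch():
    model = TrainedModel(
        family="naive_bayes", params={}, estimator=_FixedProba(0.9),
        feature_names=("a", "b"),
    )
    empty = pd.DataFrame(columns=["a", "b"])
    series, proba = predict_epochs(model, empty)
    assert len(series) == 0 and proba.size == 0
    with pytest.raises(ValueError, match="missing.*model features"):
        predict_epochs(model, pd.DataFrame({"a": [1.0]}))


def test_dataset_validation():
    with pytest.raises(ValueError, match="labels"):
        LabeledDataset(matrix=pd.DataFrame({"a": [1.0, 2.0]}), labels=np.array([1]))
    with pytest.raises(ValueError, match="binary"):
        LabeledDataset(matrix=pd.DataFrame({"a": [1.0, 2.0]}), labels=np.array([1, 2]))
    with pytest.raises(ValueError, match="unknown model family"):
        make_estimator("boosting", {})
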