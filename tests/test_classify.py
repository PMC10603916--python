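"""Feature ranking, kNN/LDA evaluation and the binary cascade."""

import numpy as np
import pandas as pd
import pytest

from postura.classify import (
    EvalScheme, LabeledDataset, ModelSpec, PRESET_FEATURE_SETS,
    cascade_evaluate, f1_from_confusion, knn_k_candidates, rank_features,
    select_features_auto, train_eval,
)
from postura.errors import SchemeDegradationError
from postura.population import make_feature_population
from postura.sites import FEATURE_NAMES


def dataset(rng, n=200, informative_gap=8.0):
    """One feature with disjoint class-conditional supports plus noise
    features."""
    y = np.array(["none"] * (n // 2) + ["mild"] * (n - n // 2))
    X = pd.DataFrame({
        "signal": np.where(y == "none", 0.0, informative_gap)
        + rng.normal(0, 0.5, n),
        "noise1": rng.normal(0, 1, n),
        "noise2": rng.normal(0, 1, n),
        "noise3": rng.normal(0, 1, n),
    })
    return LabeledDataset(X, pd.Series(y))


# ---------------------------------------------------------------------------
# ranking


@pytest.mark.parametrize("method", ["info_gain", "chi2", "relief"])
def test_disjoint_support_feature_ranked_first(method, rng):
    ds = dataset(rng)
    ranked = rank_features(ds, method)
    assert ranked[0][0] == "signal"


def test_constant_feature_scores_zero_or_warns(rng):
    X = pd.DataFrame({"const": np.ones(60), "x": rng.normal(0, 1, 60)})
    y = pd.Series(["none"] * 30 + ["mild"] * 30)
    ds = LabeledDataset(X, y)
    ig = dict(rank_features(ds, "info_gain"))
    assert ig["const"] == 0.0
    rel = dict(rank_features(ds, "relief"))
    assert rel["const"] == 0.0
    with pytest.warns(UserWarning, match="const"):
        chi = dict(rank_features(ds, "chi2"))
    assert "const" not in chi


def test_label_independent_feature_has_near_zero_relief_weight(rng):
    weights = []
    for _ in range(30):
        n = 120
        y = pd.Series(["none"] * 60 + ["mild"] * 60)
        X = pd.DataFrame({"a": rng.normal(0, 1, n),
                          "b": rng.normal(0, 1, n)})
        w = dict(rank_features(LabeledDataset(X, y), "relief"))
        weights.append(w["a"])
    assert abs(np.mean(weights)) < 0.01


def test_auto_selection_reports_provenance(rng):
    ds = dataset(rng)
    sel = select_features_auto(ds, top_m=2)
    assert "signal" in sel["selected"]
    assert set(sel["per_method"]) == {"info_gain", "chi2", "relief"}


def test_preset_feature_sets_are_valid_feature_names():
    for name, feats in PRESET_FEATURE_SETS.items():
        assert set(feats) <= set(FEATURE_NAMES), name
    assert len(PRESET_FEATURE_SETS["multiclass"]) == 9
    assert len(PRESET_FEATURE_SETS["level1"]) == 12
    assert len(PRESET_FEATURE_SETS["level2"]) == 7


# ---------------------------------------------------------------------------
# evaluation


def test_separable_classes_perfect_split_accuracy(rng):
    ds = dataset(rng, informative_gap=10.0)
    rep = train_eval(ds, ModelSpec("knn", k=1),
                     EvalScheme("split70_30", seed=0))
    assert rep.accuracy == 100.0


def test_knn_k1_on_training_data_is_perfect(rng):
    from postura.classify import _DeterministicKNN
    ds = dataset(rng)
    classes = ds.classes()
    y = np.array([classes.index(v) for v in ds.y])
    X = ds.X.to_numpy()
    model = _DeterministicKNN(1, classes).fit(X, y)
    assert (model.predict(X) == y).all()


def test_f1_from_fixed_confusion_matrix():
    cm = np.array([[8, 2], [2, 8]])
    f1, flagged = f1_from_confusion(cm)
    assert f1[0] == pytest.approx(80.0)
    assert flagged == []
    # a class never predicted nor present -> zero with flag
    cm2 = np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]])
    f1b, flaggedb = f1_from_confusion(cm2)
    assert f1b[2] == 0.0 and flaggedb == [2]


def test_accuracy_and_f1_recomputable_from_confusion(rng):
    df = make_feature_population(seed=3)
    ds = LabeledDataset.from_frame(
        df, features=list(PRESET_FEATURE_SETS["multiclass"]))
    for scheme in (EvalScheme("cv10", seed=1),
                   EvalScheme("split70_30", seed=1)):
        rep = train_eval(ds, ModelSpec("knn", k=3), scheme)
        cm = rep.confusion
        assert rep.accuracy == pytest.approx(
            100.0 * np.trace(cm) / cm.sum(), abs=1e-12)
        f1, _ = f1_from_confusion(cm)
        for c, name in enumerate(rep.classes):
            assert rep.f1_per_class[name] == pytest.approx(f1[c], abs=1e-12)
        # confusion rows sum to class counts in the evaluated partition
        truth = rep.predictions["y_true"].value_counts()
        for c, name in enumerate(rep.classes):
            assert cm[c].sum() == truth.get(name, 0)


def test_evaluation_reproducible_under_seed(rng):
    ds = dataset(rng)
    a = train_eval(ds, ModelSpec("knn", k=3), EvalScheme("cv10", seed=5))
    b = train_eval(ds, ModelSpec("knn", k=3), EvalScheme("cv10", seed=5))
    assert np.array_equal(a.confusion, b.confusion)


def test_permuted_labels_score_near_chance(rng):
    accs = []
    for i in range(60):
        n = 90
        X = pd.DataFrame(rng.normal(0, 1, (n, 4)),
                         columns=list("abcd"))
        y = pd.Series(np.repeat(["none", "mild", "moderate_severe"], n // 3))
        y = pd.Series(rng.permutation(y.values))
        ds = LabeledDataset(X, y)
        rep = train_eval(ds, ModelSpec("knn", k=5),
                         EvalScheme("split70_30", seed=i))
        accs.append(rep.accuracy)
    assert 28.0 <= np.mean(accs) <= 38.0


def test_lda_runs_and_reports_three_classes():
    df = make_feature_population(seed=4)
    ds = LabeledDataset.from_frame(df)
    rep = train_eval(ds, ModelSpec("lda", scaling=False),
                     EvalScheme("cv10", seed=0))
    assert set(rep.f1_per_class) == {"none", "mild", "moderate_severe"}
    assert 0.0 <= rep.accuracy <= 100.0


# ---------------------------------------------------------------------------
# k selection


def test_k1_among_candidates_when_1nn_is_perfect(rng):
    ds = dataset(rng, informative_gap=12.0)
    ks = knn_k_candidates(ds, EvalScheme("split70_30", seed=0),
                          k_grid=range(1, 22))
    assert 1 in ks
    assert len(ks) == 5


def test_small_grid_returned_unchanged(rng):
    ds = dataset(rng)
    ks = knn_k_candidates(ds, EvalScheme("split70_30", seed=0),
                          k_grid=[3, 5, 7, 9, 11])
    assert sorted(ks) == [3, 5, 7, 9, 11]


def test_k_candidates_deterministic(rng):
    ds = dataset(rng)
    s = EvalScheme("cv10", seed=2)
    assert knn_k_candidates(ds, s) == knn_k_candidates(ds, s)


# ---------------------------------------------------------------------------
# cascade


def test_cascade_level2_evaluates_on_with_evidence_subset():
    df = make_feature_population(seed=5)  # 16/25/16
    ds = LabeledDataset.from_frame(df)
    r1, r2, comb = cascade_evaluate(ds, ModelSpec("knn", k=5),
                                    ModelSpec("knn", k=3),
                                    EvalScheme("cv10", seed=0))
    assert r1.confusion.sum() == 57
    assert r2.confusion.sum() == 41           # the with-evidence subjects
    assert set(r2.classes) == {"mild", "moderate_severe"}
    assert comb.confusion.sum() == 57


def test_forced_none_level1_chains_no_evidence_predictions():
    df = make_feature_population(seed=6)
    # majority class of the level-1 merge is "evidence", so flip: build a
    # dataset where "none" dominates
    extra = df[df.label == "none"]
    df3 = pd.concat([df, extra, extra, extra], ignore_index=True)
    df3["subject_id"] = [f"S{i}" for i in range(len(df3))]
    ds = LabeledDataset.from_frame(df3)
    r1, r2, comb = cascade_evaluate(ds, ModelSpec("majority"),
                                    ModelSpec("knn", k=3),
                                    EvalScheme("split70_30", seed=0))
    assert set(comb.predictions["y_pred"]) == {"none"}


def test_cascade_requires_three_classes(rng):
    ds = dataset(rng)
    with pytest.raises(ValueError):
        cascade_evaluate(ds, ModelSpec("knn"), ModelSpec("knn"),
                         EvalScheme("split70_30", seed=0))


def test_cv10_infeasible_on_tiny_evidence_subset():
    df = make_feature_population(
        n_per_class={"none": 20, "mild": 8, "moderate_severe": 8},
        effects={"none": {}, "mild": {}, "moderate_severe": {}},
        noise_sd=1.0, seed=0)
    ds = LabeledDataset.from_frame(df)
    with pytest.raises(SchemeDegradationError):
        cascade_evaluate(ds, ModelSpec("knn", k=3), ModelSpec("knn", k=3),
                         EvalScheme("cv10", seed=0))


def test_cascade_beats_or_matches_multiclass_on_separated_data():
    df = make_feature_population(seed=7)
    ds = LabeledDataset.from_frame(df)
    scheme = EvalScheme("split70_30", seed=1)
    multi = train_eval(ds, ModelSpec("knn", k=3), scheme)
    _, _, comb = cascade_evaluate(ds, ModelSpec("knn", k=3),
                                  ModelSpec("knn", k=3), scheme)
    # empirical comparison on well-separated classes, not a theorem
    assert comb.accuracy >= multi.accuracy - 10.0


def test_model_and_scheme_validation():
    with pytest.raises(ValueError):
        ModelSpec("svm")
    with pytest.raises(ValueError):
        ModelSpec("knn", k=0)
    with pytest.raises(ValueError):
        EvalScheme("loocv")
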