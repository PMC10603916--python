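"""Feature ranking and screening classifiers.

Three filter rankings (information gain on equal-frequency 4-bin
discretized features, the chi-squared statistic of the binned
feature × class table, and ReliefF with 5 hits/misses) order the
features; LDA and a deterministic kNN are evaluated with stratified
10-fold cross-validation or a stratified 70/30 train/test split, in a
three-class configuration or as a two-level binary cascade (level 1:
any-evidence vs none; level 2: mild vs moderate/severe among the
with-evidence subjects).

Reported metrics are the accuracy and one-vs-rest F1 per class, both in
percent, with the confusion matrix retained so every figure can be
recomputed from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .errors import SchemeDegradationError, StratificationError

CLASS_ORDER = ("none", "mild", "moderate_severe", "evidence")

#: fixed feature-set presets used by the original screening configuration
PRESET_FEATURE_SETS = {
    "multiclass": ("ASA", "AJND_L", "AAD_L", "AAD_R", "PSISHA",
                   "PSISLA_R", "APD_L", "APD_R", "LLC_L"),
    "level1": ("AHA_A", "ASA", "AAD_L", "TKA", "LLA", "PKLA_L", "PKLA_R",
               "APD_L", "APD_R", "PLLL_R", "TKC_L", "LLC_L"),
    "level2": ("ASISLA_R", "AKLA_R", "AAD_L", "AAD_R", "APD_L", "APD_R",
               "LLC_L"),
}

DEFAULT_K_GRID = tuple(range(1, 22))


@dataclass(frozen=True)
class LabeledDataset:
    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.X.isna().any().any():
            raise ValueError("missing feature values must be resolved first")
        if self.y.nunique() < 2:
            raise ValueError("at least 2 classes required")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label",
                   features=None) -> "LabeledDataset":
        feats = list(features) if features is not None else [
            c for c in df.columns if c not in (label_col, "subject_id")]
        return cls(df[feats].astype(float), df[label_col])

    def classes(self) -> list:
        present = set(self.y)
        ordered = [c for c in CLASS_ORDER if c in present]
        return ordered + sorted(present - set(ordered))

    def subset(self, mask) -> "LabeledDataset":
        return LabeledDataset(self.X[mask], self.y[mask])


@dataclass(frozen=True)
class ModelSpec:
    kind: str                       # lda | knn | majority
    k: int = 5                      # knn only
    scaling: bool = True            # z-score on training statistics

    def __post_init__(self):
        if self.kind not in ("lda", "knn", "majority"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "knn" and self.k < 1:
            raise ValueError("k must be >= 1")

    def describe(self) -> str:
        return f"knn(k={self.k})" if self.kind == "knn" else self.kind


@dataclass(frozen=True)
class EvalScheme:
    kind: str                       # cv10 | split70_30
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("cv10", "split70_30"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")

    def describe(self) -> str:
        return self.kind


@dataclass
class EvalReport:
    accuracy: float                 # percent
    f1_per_class: dict              # class -> percent
    confusion: np.ndarray           # rows true, cols predicted
    classes: list
    model: str
    scheme: str
    zero_division_classes: list = field(default_factory=list)
    predictions: pd.DataFrame | None = None  # index, y_true, y_pred


# ---------------------------------------------------------------------------
# feature ranking


def _equal_frequency_bins(x: np.ndarray, bins: int = 4) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _info_gain(x: np.ndarray, y_codes: np.ndarray, n_classes: int) -> float:
    b = _equal_frequency_bins(x)
    total = np.bincount(y_codes, minlength=n_classes)
    h_y = _entropy(total)
    h_cond = 0.0
    n = len(x)
    for bv in np.unique(b):
        sel = b == bv
        h_cond += sel.sum() / n * _entropy(
            np.bincount(y_codes[sel], minlength=n_classes))
    return h_y - h_cond


def _chi2(x: np.ndarray, y_codes: np.ndarray, n_classes: int) -> float | None:
    b = _equal_frequency_bins(x)
    bin_vals = np.unique(b)
    if len(bin_vals) < 2:
        return None  # constant feature: no contingency table
    table = np.zeros((len(bin_vals), n_classes))
    for i, bv in enumerate(bin_vals):
        table[i] = np.bincount(y_codes[b == bv], minlength=n_classes)
    expected = table.sum(1, keepdims=True) * table.sum(0, keepdims=True) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(cells.sum())


def _relieff(X: np.ndarray, y_codes: np.ndarray, k: int = 5) -> np.ndarray:
    """ReliefF weights: all instances, k nearest hits and k nearest
    misses per other class, min–max scaled features, miss contributions
    weighted by class prior."""
    n, p = X.shape
    rng_span = X.max(0) - X.min(0)
    span = np.where(rng_span > 0, rng_span, 1.0)
    Xs = (X - X.min(0)) / span
    classes, counts = np.unique(y_codes, return_counts=True)
    priors = counts / n
    w = np.zeros(p)
    for c_i, c in enumerate(classes):
        idx_c = np.flatnonzero(y_codes == c)
        if len(idx_c) < 2:
            continue
        kh = min(k, len(idx_c) - 1)
        nn_hit = NearestNeighbors(n_neighbors=kh + 1).fit(Xs[idx_c])
        _, hit_idx = nn_hit.kneighbors(Xs[idx_c])
        for row, i in enumerate(idx_c):
            hits = idx_c[hit_idx[row][1:]]
            w -= np.abs(Xs[i] - Xs[hits]).mean(0) / n
            p_y = priors[c_i]
            for m_i, m in enumerate(classes):
                if m == c:
                    continue
                idx_m = np.flatnonzero(y_codes == m)
                km = min(k, len(idx_m))
                nn_miss = NearestNeighbors(n_neighbors=km).fit(Xs[idx_m])
                _, miss_idx = nn_miss.kneighbors(Xs[i][None, :])
                misses = idx_m[miss_idx[0]]
                w += (priors[m_i] / (1 - p_y)) * \
                    np.abs(Xs[i] - Xs[misses]).mean(0) / n
    return w


def rank_features(ds: LabeledDataset, method: str) -> list:
    """Ordered ``(feature, score)`` list, best first; ties broken by
    feature name.  Constant features score 0 for info_gain/relief and
    are excluded from chi2 with a warning."""
    if ds.X.shape[1] < 2:
        raise ValueError("at least 2 features required")
    classes = ds.classes()
    y_codes = np.array([classes.index(v) for v in ds.y])
    X = ds.X.to_numpy(dtype=float)
    scores = {}
    if method == "info_gain":
        for j, name in enumerate(ds.X.columns):
            x = X[:, j]
            scores[name] = 0.0 if np.ptp(x) == 0 else _info_gain(
                x, y_codes, len(classes))
    elif method == "chi2":
        for j, name in enumerate(ds.X.columns):
            s = _chi2(X[:, j], y_codes, len(classes))
            if s is None:
                warnings.warn(f"constant feature {name!r} excluded from chi2")
                continue
            scores[name] = s
    elif method == "relief":
        w = _relieff(X, y_codes)
        const = np.ptp(X, axis=0) == 0
        for j, name in enumerate(ds.X.columns):
            scores[name] = 0.0 if const[j] else float(w[j])
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def select_features_auto(ds: LabeledDataset, top_m: int = 5) -> dict:
    """Union of each ranking method's top-m features, with provenance."""
    per_method = {m: [f for f, _ in rank_features(ds, m)[:top_m]]
                  for m in ("info_gain", "chi2", "relief")}
    union = sorted({f for feats in per_method.values() for f in feats})
    return {"selected": union, "per_method": per_method}


# ---------------------------------------------------------------------------
# deterministic kNN (Euclidean on z-scored features; vote ties broken by
# smaller mean neighbor distance, then smaller class index)


class _DeterministicKNN:
    def __init__(self, k: int, classes: list):
        self.k = k
        self.classes = classes

    def fit(self, X, y_codes):
        self._nn = NearestNeighbors(n_neighbors=self.k).fit(X)
        self._y = np.asarray(y_codes)
        return self

    def predict(self, X):
        dist, idx = self._nn.kneighbors(X)
        out = np.empty(len(X), dtype=int)
        for i in range(len(X)):
            labels = self._y[idx[i]]
            votes = np.bincount(labels, minlength=len(self.classes))
            top = votes.max()
            tied = np.flatnonzero(votes == top)
            if len(tied) == 1:
                out[i] = tied[0]
            else:
                means = [dist[i][labels == c].mean() for c in tied]
                out[i] = tied[int(np.argmin(means))]  # argmin: first = smaller class
        return out


class _Majority:
    def fit(self, X, y_codes):
        self._mode = int(np.bincount(y_codes).argmax())
        return self

    def predict(self, X):
        return np.full(len(X), self._mode, dtype=int)


def _make_model(spec: ModelSpec, classes: list):
    if spec.kind == "lda":
        class _LDA:
            def fit(self, X, y):
                self._m = LinearDiscriminantAnalysis().fit(X, y)
                return self

            def predict(self, X):
                return self._m.predict(X)
        return _LDA()
    if spec.kind == "knn":
        return _DeterministicKNN(spec.k, classes)
    return _Majority()


def _zscore_fit(X_train):
    mu = X_train.mean(0)
    sd = X_train.std(0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _confusion(y_true, y_pred, n_classes):
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


def f1_from_confusion(cm: np.ndarray) -> tuple:
    """One-vs-rest F1 (%) per class from a confusion matrix; classes with
    zero TP+FP+FN report 0 and are flagged."""
    f1 = []
    flagged = []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        denom = 2 * tp + fp + fn
        if denom == 0:
            f1.append(0.0)
            flagged.append(c)
        else:
            f1.append(100.0 * 2 * tp / denom)
    return f1, flagged


def _check_training_classes(y_codes_train, n_classes, where):
    present = set(np.unique(y_codes_train))
    if len(present) < n_classes:
        raise StratificationError(
            f"{where}: training portion lacks class(es) "
            f"{sorted(set(range(n_classes)) - present)}")


def _fit_predict(spec, classes, X_tr, y_tr, X_te):
    if spec.scaling:
        mu, sd = _zscore_fit(X_tr)
        X_tr = (X_tr - mu) / sd
        X_te = (X_te - mu) / sd
    model = _make_model(spec, classes).fit(X_tr, y_tr)
    return model.predict(X_te)


def train_eval(ds: LabeledDataset, model: ModelSpec,
               scheme: EvalScheme) -> EvalReport:
    """Evaluate one model under one validation scheme.

    For 10-fold CV the metrics are pooled over the union of out-of-fold
    predictions; for the 70/30 split they come from the single test set.
    kNN features are z-scored with statistics fitted on the training
    portion only.
    """
    classes = ds.classes()
    y_codes = np.array([classes.index(v) for v in ds.y])
    X = ds.X.to_numpy(dtype=float)
    index = ds.X.index

    if scheme.kind == "cv10":
        counts = np.bincount(y_codes)
        if counts.min() < 2:
            raise SchemeDegradationError(
                "10-fold CV infeasible: a class has fewer than 2 members")
        splitter = StratifiedKFold(n_splits=10, shuffle=True,
                                   random_state=scheme.seed)
        y_true = np.empty(len(X), dtype=int)
        y_pred = np.empty(len(X), dtype=int)
        eval_idx = np.arange(len(X))
        for tr, te in splitter.split(X, y_codes):
            _check_training_classes(y_codes[tr], len(classes), "cv10 fold")
            y_pred[te] = _fit_predict(model, classes, X[tr], y_codes[tr], X[te])
            y_true[te] = y_codes[te]
    else:
        tr, te = train_test_split(
            np.arange(len(X)), test_size=0.3,
            stratify=y_codes if scheme.stratified else None,
            random_state=scheme.seed)
        _check_training_classes(y_codes[tr], len(classes), "70/30 split")
        y_pred = _fit_predict(model, classes, X[tr], y_codes[tr], X[te])
        y_true = y_codes[te]
        eval_idx = te

    cm = _confusion(y_true, y_pred, len(classes))
    acc = 100.0 * np.trace(cm) / cm.sum()
    f1, flagged = f1_from_confusion(cm)
    preds = pd.DataFrame({
        "y_true": [classes[c] for c in y_true],
        "y_pred": [classes[c] for c in y_pred],
    }, index=index[eval_idx])
    return EvalReport(
        accuracy=float(acc),
        f1_per_class={classes[c]: f1[c] for c in range(len(classes))},
        confusion=cm, classes=classes,
        model=model.describe(), scheme=scheme.describe(),
        zero_division_classes=[classes[c] for c in flagged],
        predictions=preds)


def knn_k_candidates(ds: LabeledDataset, scheme: EvalScheme,
                     k_grid=DEFAULT_K_GRID, n_best: int = 5) -> list:
    """The ``n_best`` k values with the lowest error rate under the given
    scheme; ties break toward smaller k."""
    n = len(ds.X)
    n_train = int(np.floor(0.9 * n)) if scheme.kind == "cv10" else int(0.7 * n)
    feasible = [k for k in k_grid if 1 <= k < n_train]
    if not feasible:
        raise ValueError("no feasible k in grid")
    errors = []
    for k in feasible:
        rep = train_eval(ds, ModelSpec("knn", k=k), scheme)
        errors.append((100.0 - rep.accuracy, k))
    errors.sort()
    best = [k for _, k in errors[:n_best]]
    if len(best) < n_best:
        warnings.warn(f"only {len(best)} feasible k values available")
    return best


# ---------------------------------------------------------------------------
# two-level binary cascade

EVIDENCE = "evidence"


def _merge_evidence(y: pd.Series) -> pd.Series:
    return y.map(lambda v: "none" if v == "none" else EVIDENCE)


def cascade_evaluate(ds: LabeledDataset, level1: ModelSpec, level2: ModelSpec,
                     scheme: EvalScheme,
                     level1_features=None, level2_features=None) -> tuple:
    """Two-level binary cascade on a three-class dataset.

    Level 1 separates any-evidence from none on all subjects; level 2
    grades mild vs moderate/severe on the true with-evidence subjects.
    The combined three-class report chains level-1 "evidence" predictions
    through level 2 (out-of-fold level-2 predictions where the subject
    was in the level-2 evaluation; otherwise a level-2 model trained on
    all with-evidence subjects).
    """
    present = set(ds.y)
    if not {"mild", "moderate_severe"} <= present:
        raise ValueError("cascade requires three-class labels")

    X1 = ds.X if level1_features is None else ds.X[list(level1_features)]
    ds1 = LabeledDataset(X1, _merge_evidence(ds.y))
    rep1 = train_eval(ds1, level1, scheme)

    ev_mask = ds.y != "none"
    X2_all = ds.X[ev_mask] if level2_features is None \
        else ds.X.loc[ev_mask, list(level2_features)]
    ds2 = LabeledDataset(X2_all, ds.y[ev_mask])
    if scheme.kind == "cv10" and len(ds2.y) < 2 * 10:
        raise SchemeDegradationError(
            f"level-2 evaluation set has {len(ds2.y)} subjects; "
            "10-fold CV needs at least 20")
    rep2 = train_eval(ds2, level2, scheme)

    # fallback level-2 model trained on every with-evidence subject
    classes2 = ds2.classes()
    y2_codes = np.array([classes2.index(v) for v in ds2.y])
    X2 = ds2.X.to_numpy(dtype=float)
    if level2.scaling:
        mu, sd = _zscore_fit(X2)
        X2s = (X2 - mu) / sd
    else:
        mu, sd = 0.0, 1.0
        X2s = X2
    full2 = _make_model(level2, classes2).fit(X2s, y2_codes)

    level2_oof = rep2.predictions["y_pred"] if rep2.predictions is not None else None
    combined_true, combined_pred, combined_index = [], [], []
    for idx, row in rep1.predictions.iterrows():
        combined_index.append(idx)
        combined_true.append(ds.y.loc[idx])
        if row["y_pred"] == "none":
            combined_pred.append("none")
        elif level2_oof is not None and idx in level2_oof.index:
            combined_pred.append(level2_oof.loc[idx])
        else:
            x = ds2.X.columns
            xv = (ds.X.loc[idx, x].to_numpy(dtype=float) - mu) / sd
            combined_pred.append(classes2[int(full2.predict(xv[None, :])[0])])

    classes3 = ds.classes()
    t_codes = [classes3.index(v) for v in combined_true]
    p_codes = [classes3.index(v) for v in combined_pred]
    cm = _confusion(t_codes, p_codes, len(classes3))
    acc = 100.0 * np.trace(cm) / cm.sum()
    f1, flagged = f1_from_confusion(cm)
    combined = EvalReport(
        accuracy=float(acc),
        f1_per_class={classes3[c]: f1[c] for c in range(len(classes3))},
        confusion=cm, classes=classes3,
        model=f"cascade({level1.describe()}|{level2.describe()})",
        scheme=scheme.describe(),
        zero_division_classes=[classes3[c] for c in flagged],
        predictions=pd.DataFrame({"y_true": combined_true,
                                  "y_pred": combined_pred},
                                 index=combined_index))
    return rep1, rep2, combined
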