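"""Graph-feature assembly, Welch-t filter feature selection, leave-one-out
cross-validation over five classifiers, and an AdaBoost.M1 + random
undersampling ensemble (RUSBoost) for the imbalanced two-group problem.

Feature layout per mood condition: for each metric in {cc, strength}, one
column per channel x band x target frequency at the feature density, plus
global efficiency per band x target frequency — with 64 channels, 6 bands
and 8 target frequencies that is 64*96 + 48 = 6192 named columns. The
positive class is the HS (minority) group throughout, so sensitivity is the
HS detection rate. Feature ranking is re-fit inside every training fold
(no leakage); a deliberately leaky global mode exists behind a flag for
comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .stats import welch_t

POSITIVE_CLASS = "HS-like"
NEGATIVE_CLASS = "LS-like"


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def feature_name(metric: str, channel: str, band: str, freq) -> str:
    return f"{metric}.{channel}.{band}.{freq}"


def assemble_features(
    metric_records: pd.DataFrame,
    channels: tuple[str, ...],
    bands: tuple[str, ...],
    target_frequencies: tuple,
) -> pd.DataFrame:
    """Pivot long-format graph metrics into a subjects x features table.

    ``metric_records`` needs columns: subject, group, band, target_frequency,
    channel (or 'GLOBAL' for ge), metric ('cc'|'strength'|'ge'), value — all
    at the feature density. Raises if any (subject, band, frequency) cell is
    missing. The returned frame is indexed by subject and carries the group
    labels in ``df.attrs['groups']``.
    """
    req = {"subject", "group", "band", "target_frequency", "channel", "metric", "value"}
    missing_cols = req - set(metric_records.columns)
    if missing_cols:
        raise ValueError(f"metric records missing columns: {sorted(missing_cols)}")
    expected = []
    for metric in ("cc", "strength"):
        for ch in channels:
            for b in bands:
                for f in target_frequencies:
                    expected.append((metric, ch, b, f))
    for b in bands:
        for f in target_frequencies:
            expected.append(("ge", "GLOBAL", b, f))
    rec = metric_records.copy()
    rec["feature"] = [
        feature_name(m, c, b, f)
        for m, c, b, f in zip(rec["metric"], rec["channel"], rec["band"], rec["target_frequency"])
    ]
    wide = rec.pivot_table(index="subject", columns="feature", values="value", aggfunc="first")
    names = [feature_name(*e) for e in expected]
    absent = [n for n in names if n not in wide.columns]
    if absent:
        raise ValueError(f"missing feature cells, e.g. {absent[:5]} ({len(absent)} total)")
    wide = wide[names]
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing values after assembly in {bad[:5]}")
    groups = rec.drop_duplicates("subject").set_index("subject")["group"]
    wide.attrs["groups"] = groups.loc[wide.index]
    return wide


# ---------------------------------------------------------------------------
# Welch-t filter ranking
# ---------------------------------------------------------------------------

def _abs_welch(a: np.ndarray, b: np.ndarray) -> float:
    """|Welch t| with graceful degradation for degenerate columns.

    A class with a single row contributes zero variance (its term drops from
    the denominator); columns constant in both classes score 0.
    """
    va = a.var(ddof=1) / len(a) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) / len(b) if len(b) > 1 else 0.0
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / denom)


def rank_features_welch(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column indices sorted by |Welch t| descending (stable ties by index).

    Constant-in-both-groups columns get |t| = 0.
    """
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes in the training rows")
    a = X[y == classes[0]]
    b = X[y == classes[1]]
    tvals = np.zeros(X.shape[1])
    for c in range(X.shape[1]):
        tvals[c] = _abs_welch(a[:, c], b[:, c])
    # stable sort on (-|t|, index)
    return np.lexsort((np.arange(len(tvals)), -tvals))


# ---------------------------------------------------------------------------
# RUSBoost
# ---------------------------------------------------------------------------

class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost.M1 with per-round random undersampling of the majority class.

    Each boosting round draws a balanced training sample: all minority-class
    rows plus a majority-class subsample of the same size drawn (without
    replacement) with probability proportional to the current AdaBoost
    sample weights. The weak learner (a shallow CART tree) is fit on that
    sample; weighted error, learner weight and the multiplicative weight
    update follow the AdaBoost.M1 schedule on the *full* training set.
    Prediction is the weighted vote of the rounds. With ``undersample=False``
    the algorithm reduces to plain AdaBoost.M1.
    """

    def __init__(
        self,
        n_rounds: int = 100,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        undersample: bool = True,
        random_state: int | None = None,
    ):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.undersample = undersample
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RUSBoost here is a two-class ensemble")
        counts = [np.sum(y == c) for c in self.classes_]
        minority = self.classes_[int(np.argmin(counts))]
        if min(counts) < 2:
            raise ValueError("minority class needs at least 2 samples")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        yi = (y == self.classes_[1]).astype(int)  # 0/1 encoding
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y != minority)
        n_skipped = 0
        while len(self.estimators_) < self.n_rounds:
            if self.undersample and len(maj_idx) > len(min_idx):
                pw = w[maj_idx]
                pw = pw / pw.sum() if pw.sum() > 0 else None
                pick = rng.choice(maj_idx, size=len(min_idx), replace=False, p=pw)
                idx = np.concatenate([min_idx, pick])
            else:
                idx = np.arange(n)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], yi[idx], sample_weight=w[idx])
            pred = tree.predict(X)
            miss = pred != yi
            err = float(np.sum(w * miss) / np.sum(w))
            if err >= 0.5:
                # a bad stochastic resample: skip this round and redraw
                n_skipped += 1
                if n_skipped >= self.n_rounds:
                    import warnings

                    warnings.warn("weak learner no better than chance; stopping early")
                    break
                continue
            # floor the error so perfect rounds keep a finite vote and boosting
            # continues to average over many balanced resamples
            err_eff = max(err, 1.0 / (2 * n))
            alpha = self.learning_rate * 0.5 * np.log((1 - err_eff) / err_eff)
            w = w * np.exp(2 * alpha * miss)  # AdaBoost.M1: up-weight misses
            w = w / w.sum()
            self.estimators_.append(tree)
            self.alphas_.append(float(alpha))
        if not self.estimators_:  # degenerate: fall back to a single tree
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(X, yi, sample_weight=w)
            self.estimators_ = [tree]
            self.alphas_ = [1.0]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        score = np.zeros(len(X))
        for tree, a in zip(self.estimators_, self.alphas_):
            score += a * (2.0 * tree.predict(X) - 1.0)
        return score

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# Classifier registry and LOO-CV
# ---------------------------------------------------------------------------

def make_classifier(name: str, seed: int | None = None):
    """Classifier by registry name: dt | knn | lda | svm | rusboost."""
    if name == "dt":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "rusboost":
        return RUSBoostClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")

CLASSIFIER_NAMES = ("dt", "knn", "lda", "svm", "rusboost")
#: classifiers fit on z-scored features (trees are scale-invariant)
_SCALED = {"knn", "lda", "svm"}


@dataclass
class ClassificationResult:
    """Aggregated held-out predictions of a leave-one-out run."""

    classifier: str
    k_features: int
    predictions: pd.DataFrame  # subject, true, predicted
    selected_features: list = field(default_factory=list)  # per-fold column names
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.predictions["true"].to_numpy()
        p = self.predictions["predicted"].to_numpy()
        self.tp = int(np.sum((t == POSITIVE_CLASS) & (p == POSITIVE_CLASS)))
        self.fn = int(np.sum((t == POSITIVE_CLASS) & (p != POSITIVE_CLASS)))
        self.tn = int(np.sum((t == NEGATIVE_CLASS) & (p == NEGATIVE_CLASS)))
        self.fp = int(np.sum((t == NEGATIVE_CLASS) & (p != NEGATIVE_CLASS)))
        self.metrics = metrics_from_confusion(self.tp, self.fn, self.tn, self.fp)

    def selection_frequency(self) -> pd.Series:
        """How often each feature was selected across folds, descending."""
        flat = [f for fold in self.selected_features for f in fold]
        return pd.Series(flat).value_counts()


def truncate2(x: float) -> float:
    """Truncate (not round) a percentage to two decimals, report-style."""
    return np.trunc(x * 100.0) / 100.0


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Accuracy / sensitivity / specificity as two-decimal-truncated
    percentages plus F1 as a proportion.

    Sensitivity is the HS (positive, minority) detection rate TP/(TP+FN);
    specificity is TN/(TN+FP). Undefined ratios (zero denominators) are
    returned as NaN and flagged.
    """
    if min(tp, fn, tn, fp) < 0 or tp + fn + tn + fp == 0:
        raise ValueError("confusion counts must be non-negative with a positive total")
    total = tp + fn + tn + fp

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    acc = ratio(tp + tn, total)
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    return {
        "accuracy": truncate2(acc * 100),
        "sensitivity": truncate2(sens * 100),
        "specificity": truncate2(spec * 100),
        "f1": truncate2(f1),
        "undefined": any(np.isnan(v) for v in (acc, sens, spec, f1)),
    }


def loo_cv(
    features: pd.DataFrame,
    groups: pd.Series | np.ndarray | None = None,
    classifier: str = "rusboost",
    k: int = 10,
    seed: int = 0,
    leaky_global_ranking: bool = False,
) -> ClassificationResult:
    """Leave-one-out CV with in-fold Welch-t feature selection.

    Per fold: rank features on the training rows only, keep the top ``k``,
    z-score using training statistics (for the scale-sensitive classifiers),
    fit, and predict the held-out subject. ``leaky_global_ranking`` ranks
    once on all subjects (for leakage comparisons only).
    """
    X = features.to_numpy(dtype=float)
    if groups is None:
        groups = features.attrs["groups"]
    y = np.asarray(groups)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    k = min(k, X.shape[1])
    global_rank = rank_features_welch(X, y)[:k] if leaky_global_ranking else None
    preds = []
    selections = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, ytr = X[tr], y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError("training fold lost a class")
        sel = global_rank if global_rank is not None else rank_features_welch(Xtr, ytr)[:k]
        selections.append([features.columns[j] for j in sel])
        Xtr_s, Xte_s = Xtr[:, sel], X[i : i + 1, sel]
        if classifier in _SCALED:
            mu = Xtr_s.mean(axis=0)
            sd = Xtr_s.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xtr_s = (Xtr_s - mu) / sd
            Xte_s = (Xte_s - mu) / sd
        clf = make_classifier(classifier, seed=seed + i)
        clf.fit(Xtr_s, ytr)
        preds.append((features.index[i], y[i], clf.predict(Xte_s)[0]))
    pred_df = pd.DataFrame(preds, columns=["subject", "true", "predicted"])
    return ClassificationResult(
        classifier=classifier, k_features=k, predictions=pred_df,
        selected_features=selections,
    )


def evaluate_classifiers(
    features: pd.DataFrame,
    groups=None,
    classifiers=CLASSIFIER_NAMES,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """LOO-CV metrics table across classifiers (one row per classifier)."""
    rows = []
    for name in classifiers:
        res = loo_cv(features, groups=groups, classifier=name, k=k, seed=seed)
        rows.append(
            {
                "classifier": name,
                "k_features": res.k_features,
                "tp": res.tp,
                "fn": res.fn,
                "tn": res.tn,
                "fp": res.fp,
                **{m: res.metrics[m] for m in ("accuracy", "sensitivity", "specificity", "f1")},
            }
        )
    return pd.DataFrame(rows)
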