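"""Emotion classification: Fisher LDA, plugin learners, CV, evaluation.

The discriminant is implemented from first principles: the two-class
Fisher projection w ∝ S_w^{-1}(mu_1 - mu_2) maximizes between-class mean
separation relative to pooled within-class scatter, test points are
projected onto the same line and thresholded at the midpoint of the
projected class means.  Multi-class problems are handled by pairwise
voting over the two-class machines, staying faithful to the two-class
projection mechanism.

External learners (SVM, MLP, ...) plug in behind the same fit/predict
contract; cross-validation schemes cover the leave-one-block-out design
(a condition x block grid, one block per fold), leave-one-subject-out,
and seeded stratified k-fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .features import FeatureTable

__all__ = [
    "TrainedModel",
    "CVScheme",
    "EvalReport",
    "lda_train",
    "predict",
    "PLUGIN_CLASSIFIERS",
    "plugin_classifier",
    "cv_split",
    "evaluate",
    "compare_feature_sets",
    "subject_similarity_select",
    "fisher_criterion",
]

LDA_RIDGE_FACTOR = 1e-6  # scatter regularization: eps = factor * mean diagonal


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------

def _fisher_direction(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, float]:
    """Two-class Fisher projection and midpoint threshold.

    Pooled within-class scatter is ridge-regularized so duplicated or
    collinear features stay well-posed.
    """
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    s_w = np.zeros((x1.shape[1], x1.shape[1]))
    for x, mu in ((x1, mu1), (x2, mu2)):
        d = x - mu
        s_w += d.T @ d
    eps = LDA_RIDGE_FACTOR * max(np.mean(np.diag(s_w)), 1e-12)
    s_w += eps * np.eye(s_w.shape[0])
    w = np.linalg.solve(s_w, mu1 - mu2)
    threshold = float(w @ (mu1 + mu2) / 2.0)
    return w, threshold


def fisher_criterion(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """J(w) = (w.(mu1-mu2))^2 / (w' S_w w) for a two-class problem."""
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("fisher_criterion is defined for two classes")
    x1, x2 = x[y == classes[0]], x[y == classes[1]]
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    s_w = np.zeros((x.shape[1], x.shape[1]))
    for xs, mu in ((x1, mu1), (x2, mu2)):
        d = xs - mu
        s_w += d.T @ d
    denom = float(w @ s_w @ w)
    if denom <= 0:
        return 0.0
    return float((w @ (mu1 - mu2)) ** 2 / denom)


@dataclass
class TrainedModel:
    """A fitted classifier: the LDA pairwise machines or a plugin learner."""

    kind: str                       # "lda" | "plugin"
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    pairwise: list[dict] = field(default_factory=list)   # lda only
    plugin: Any = None                                   # fitted estimator
    plugin_name: str = ""

    def to_json(self, path: str | Path) -> None:
        if self.kind != "lda":
            raise ValidationError("only LDA models serialize to JSON")
        payload = {
            "kind": self.kind,
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "pairwise": [
                {"a": p["a"], "b": p["b"], "w": list(map(float, p["w"])),
                 "threshold": p["threshold"]}
                for p in self.pairwise
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        pairwise = [
            {"a": p["a"], "b": p["b"], "w": np.asarray(p["w"]),
             "threshold": p["threshold"]}
            for p in payload["pairwise"]
        ]
        return cls("lda", tuple(payload["classes"]),
                   tuple(payload["feature_names"]), pairwise)


def _as_matrix(table: "FeatureTable | _SubsetTable | np.ndarray",
               feature_names: Sequence[str] | None = None
               ) -> tuple[np.ndarray, tuple[str, ...]]:
    if hasattr(table, "feature_names") and hasattr(table, "matrix"):
        names = tuple(table.feature_names)
        if feature_names is not None:
            missing = [n for n in feature_names if n not in names]
            if missing:
                raise ValidationError(f"feature table lacks columns {missing}")
            extra = [n for n in names if n not in set(feature_names)]
            if extra:
                raise ValidationError(f"unexpected feature columns {extra}")
            return table.matrix(list(feature_names)), tuple(feature_names)
        return table.matrix(), names
    x = np.asarray(table, dtype=float)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(x.shape[1]))
    return x, names


def lda_train(table: FeatureTable | np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit Fisher LDA (pairwise voting for more than two classes)."""
    x, names = _as_matrix(table)
    y = np.asarray(y)
    classes = tuple(str(c) for c in np.unique(y))
    if len(classes) < 2:
        raise ValidationError("lda_train needs at least two classes present")
    counts = {c: int(np.sum(y.astype(str) == c)) for c in classes}
    lacking = [c for c, n in counts.items() if n < 2]
    if lacking:
        raise ValidationError(f"classes with fewer than 2 samples: {lacking}")
    pairwise = []
    ys = y.astype(str)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            w, thr = _fisher_direction(x[ys == a], x[ys == b])
            pairwise.append({"a": a, "b": b, "w": w, "threshold": thr})
    return TrainedModel("lda", classes, names, pairwise=pairwise)


def predict(model: TrainedModel, table: FeatureTable | np.ndarray) -> np.ndarray:
    """Predict labels; feature columns are matched by name and must agree
    exactly with the training columns."""
    x, _ = _as_matrix(table, model.feature_names)
    if model.kind == "plugin":
        return np.asarray(model.plugin.predict(x)).astype(str)
    n = x.shape[0]
    votes = {c: np.zeros(n) for c in model.classes}
    margins = {c: np.zeros(n) for c in model.classes}
    for p in model.pairwise:
        proj = x @ p["w"] - p["threshold"]
        a_wins = proj >= 0
        votes[p["a"]] += a_wins
        votes[p["b"]] += ~a_wins
        margins[p["a"]] += proj
        margins[p["b"]] -= proj
    out = np.empty(n, dtype=object)
    for i in range(n):
        # most votes; ties broken by aggregate projected margin, then order
        best = max(model.classes,
                   key=lambda c: (votes[c][i], margins[c][i]))
        out[i] = best
    return out.astype(str)


# ---------------------------------------------------------------------------
# Plugin classifiers
# ---------------------------------------------------------------------------

def _make_svm(seed: int):
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, random_state=seed))


def _make_mlp(seed: int):
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    return make_pipeline(StandardScaler(),
                         MLPClassifier(hidden_layer_sizes=(32,), max_iter=2000,
                                       random_state=seed))


def _make_knn(seed: int):
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))


def _make_logreg(seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    return make_pipeline(StandardScaler(),
                         LogisticRegression(max_iter=2000, random_state=seed))


def _make_rf(seed: int):
    from sklearn.ensemble import RandomForestClassifier
    return RandomForestClassifier(n_estimators=200, random_state=seed)


PLUGIN_CLASSIFIERS: dict[str, Callable[[int], Any]] = {
    "svm": _make_svm,
    "mlp": _make_mlp,
    "knn": _make_knn,
    "logreg": _make_logreg,
    "rf": _make_rf,
}


def plugin_classifier(name: str, seed: int = 0) -> Any:
    """A seeded external learner satisfying fit(X, y)/predict(X)."""
    if name not in PLUGIN_CLASSIFIERS:
        raise ValidationError(
            f"unregistered classifier {name!r}; registry: {sorted(PLUGIN_CLASSIFIERS)}")
    return PLUGIN_CLASSIFIERS[name](seed)


def _fit_model(spec: str, table_or_x, y: np.ndarray, seed: int) -> TrainedModel:
    if spec == "lda":
        return lda_train(table_or_x, y)
    est = plugin_classifier(spec, seed)
    x, names = _as_matrix(table_or_x)
    est.fit(x, y.astype(str))
    classes = tuple(str(c) for c in np.unique(y.astype(str)))
    return TrainedModel("plugin", classes, names, plugin=est, plugin_name=spec)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVScheme:
    """How to partition samples into folds.

    ``leave_one_block_out`` treats samples as a condition x block grid and
    leaves one block out per fold; ``leave_one_subject_out`` folds by
    subject; ``stratified_kfold`` shuffles with the given seed.
    """

    kind: str
    n_splits: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("leave_one_block_out", "leave_one_subject_out",
                             "stratified_kfold"):
            raise ValidationError(f"unknown CV scheme {self.kind!r}")


def cv_split(scheme: CVScheme, meta: pd.DataFrame,
             y: np.ndarray | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Folds as (train_indices, test_indices) pairs partitioning all rows.

    *meta* needs a ``block`` column for leave-one-block-out and a
    ``subject_id`` column for leave-one-subject-out.
    """
    n = len(meta)
    idx = np.arange(n)
    if scheme.kind == "leave_one_block_out":
        if "block" not in meta.columns:
            raise ValidationError("leave_one_block_out requires a 'block' column")
        folds = []
        for blk in sorted(meta["block"].unique(), key=str):
            test = idx[(meta["block"] == blk).to_numpy()]
            folds.append((np.setdiff1d(idx, test), test))
        return folds
    if scheme.kind == "leave_one_subject_out":
        if "subject_id" not in meta.columns:
            raise ValidationError("leave_one_subject_out requires 'subject_id'")
        folds = []
        for sid in sorted(meta["subject_id"].unique(), key=str):
            test = idx[(meta["subject_id"] == sid).to_numpy()]
            folds.append((np.setdiff1d(idx, test), test))
        return folds
    # stratified k-fold
    if y is None:
        raise ValidationError("stratified_kfold requires labels")
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=scheme.n_splits, shuffle=True,
                          random_state=scheme.seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(n), np.asarray(y).astype(str))]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Cross-validated performance summary.

    Macro accuracy is the unweighted mean of per-fold accuracies (each
    fold's correct rate averaged over folds); the confusion matrix pools
    all folds' test predictions, rows = true class, columns = predicted.
    """

    fold_accuracies: list[float]
    macro_accuracy: float
    classes: list[str]
    confusion: np.ndarray
    per_class_recall: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "macro_accuracy": float(self.macro_accuracy),
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class_recall": {k: float(v) for k, v in self.per_class_recall.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _check_no_leak(folds: list[tuple[np.ndarray, np.ndarray]], n: int) -> None:
    all_test = np.concatenate([te for _, te in folds])
    if len(np.unique(all_test)) != n or len(all_test) != n:
        raise ValidationError("CV folds do not partition the samples")
    for tr, te in folds:
        if np.intersect1d(tr, te).size:
            raise ValidationError("train/test overlap in a CV fold")


def evaluate(table: FeatureTable, labels: np.ndarray, model_spec: str,
             scheme: CVScheme, meta: pd.DataFrame | None = None,
             seed: int = 0,
             folds: list[tuple[np.ndarray, np.ndarray]] | None = None
             ) -> EvalReport:
    """Cross-validated fit/predict with the requested model and scheme."""
    y = np.asarray(labels).astype(str)
    if meta is None:
        meta = table.table[["subject_id", "trial_id"]]
    if folds is None:
        folds = cv_split(scheme, meta, y)
    _check_no_leak(folds, len(y))
    classes = sorted(str(c) for c in np.unique(y))
    cidx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    x, names = _as_matrix(table)
    for tr, te in folds:
        model = _fit_model(model_spec, _SubsetTable(x[tr], names), y[tr], seed)
        pred = predict(model, _SubsetTable(x[te], names))
        fold_acc.append(float(np.mean(pred == y[te])))
        for t, p in zip(y[te], pred):
            if p in cidx:
                confusion[cidx[t], cidx[p]] += 1
    recall = {}
    for c in classes:
        i = cidx[c]
        total = confusion[i].sum()
        recall[c] = confusion[i, i] / total if total else 0.0
    return EvalReport(fold_acc, float(np.mean(fold_acc)), classes, confusion, recall)


class _SubsetTable:
    """Array + names adapter satisfying the FeatureTable duck type used by
    lda_train/predict (avoids rebuilding pandas frames inside CV loops)."""

    def __init__(self, x: np.ndarray, names: tuple[str, ...]):
        self._x = x
        self.feature_names = list(names)

    def matrix(self, names=None) -> np.ndarray:
        if names is None or list(names) == self.feature_names:
            return self._x
        cols = [self.feature_names.index(n) for n in names]
        return self._x[:, cols]


def compare_feature_sets(table_a: FeatureTable, table_b: FeatureTable,
                         labels: np.ndarray, model_spec: str, scheme: CVScheme,
                         meta: pd.DataFrame | None = None, seed: int = 0) -> dict:
    """Paired comparison of two feature sets on identical folds.

    Reports one per-fold accuracy delta (b - a), their mean, and a
    two-sided paired t-test p-value.
    """
    y = np.asarray(labels).astype(str)
    if meta is None:
        meta = table_a.table[["subject_id", "trial_id"]]
    folds = cv_split(scheme, meta, y)
    rep_a = evaluate(table_a, y, model_spec, scheme, meta, seed, folds=folds)
    rep_b = evaluate(table_b, y, model_spec, scheme, meta, seed, folds=folds)
    deltas = [b - a for a, b in zip(rep_a.fold_accuracies, rep_b.fold_accuracies)]
    if np.allclose(deltas, 0.0):
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_rel(rep_b.fold_accuracies,
                                          rep_a.fold_accuracies)
    return {
        "fold_deltas": [float(d) for d in deltas],
        "mean_delta": float(np.mean(deltas)),
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "report_a": rep_a,
        "report_b": rep_b,
    }


# ---------------------------------------------------------------------------
# Subject selection
# ---------------------------------------------------------------------------

def subject_similarity_select(label_matrix: np.ndarray,
                              min_keep: int = 1) -> np.ndarray:
    """Select subjects whose trial-label pattern resembles the group's.

    Each subject's score is the mean Pearson correlation of their
    trial-label vector with every other subject's; subjects scoring at or
    above the group-mean score are kept (at least *min_keep*, topped up by
    score).  Returns the kept subject indices, ascending.
    """
    m = np.asarray(label_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValidationError("need a (subjects x trials) matrix with >= 2 subjects")
    n = m.shape[0]
    centered = m - m.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    off = corr.copy()
    np.fill_diagonal(off, 0.0)
    scores = off.sum(axis=1) / (n - 1)
    # small tolerance so an all-equal score vector keeps everyone
    keep = np.flatnonzero(scores >= scores.mean() - 1e-9)
    if len(keep) < min_keep:
        keep = np.argsort(-scores, kind="stable")[:min_keep]
    return np.sort(keep)
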