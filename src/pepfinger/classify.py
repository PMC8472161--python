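"""Caries-status classification from fingerprint features.

The evaluation protocol is stratified k-fold cross-validation, repeated with
bootstrap resampling of each training fold; out-of-fold predicted
probabilities are pooled across repeats for the confusion matrix (0.5 cut)
and ROC AUC. Metrics are prevalence-unweighted and derived exactly from the
confusion counts. Feature selection is a deterministic standardized-mean-
difference ranking followed by greedy de-correlation. A condensed mode
restricts the panel to the PepE features (single-peptide + inhibitors
deployment scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

MODELS = ("logistic", "knn", "tree_forward_pruned", "random_forest", "stacked")


class ClassifyError(ValueError):
    pass


@dataclass
class ClassifierReport:
    model: str
    selected_features: list[str]
    cv_scheme: str
    seed: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    accuracy: float
    auc: float
    condensed_panel: bool = False
    diagnostics: dict[str, float] = field(default_factory=dict)


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int
) -> dict[str, float]:
    """Exact prevalence-unweighted metrics from confusion counts.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision =
    TP/(TP+FP), F-measure = harmonic mean of precision and sensitivity,
    accuracy = (TP+TN)/total. Empty denominators yield 0.
    """

    def frac(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    sens = frac(tp, tp + fn)
    spec = frac(tn, tn + fp)
    prec = frac(tp, tp + fp)
    f1 = frac(2 * prec * sens, prec + sens)
    acc = frac(tp + tn, tp + fp + tn + fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f_measure": f1,
        "accuracy": acc,
    }


def select_features(
    features: pd.DataFrame, labels: np.ndarray, k: int, corr_cap: float = 0.9
) -> list[str]:
    """Rank features by |standardized mean difference|, drop near-duplicates.

    Features are ranked by the absolute pooled-SD-standardized difference of
    group means, then greedily accepted unless their absolute Pearson
    correlation with an already-kept feature exceeds ``corr_cap``.
    Deterministic for fixed input; NaN cells are ignored per feature.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ClassifyError("need exactly two classes for feature selection")
    if k > features.shape[1]:
        raise ClassifyError(f"k={k} exceeds feature count {features.shape[1]}")
    scores = {}
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        a, b = v[y == classes[0]], v[y == classes[1]]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            scores[col] = 0.0
            continue
        sp2 = (
            (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
        ) / (a.size + b.size - 2)
        if sp2 == 0:
            scores[col] = np.inf if a.mean() != b.mean() else 0.0
        else:
            scores[col] = abs(a.mean() - b.mean()) / np.sqrt(sp2)
    ranked = sorted(features.columns, key=lambda c: (-scores[c], str(c)))
    kept: list[str] = []
    filled = features.fillna(features.mean(numeric_only=True))
    for col in ranked:
        if len(kept) == k:
            break
        ok = True
        for kc in kept:
            r = np.corrcoef(
                filled[col].to_numpy(float), filled[kc].to_numpy(float)
            )[0, 1]
            if np.isfinite(r) and abs(r) > corr_cap:
                ok = False
                break
        if ok:
            kept.append(col)
    return kept


def _make_model(name: str, seed: int):
    if name == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if name == "tree_forward_pruned":
        # pre-pruned (depth/leaf limited) decision tree
        return DecisionTreeClassifier(
            max_depth=3, min_samples_leaf=3, random_state=seed
        )
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "stacked":
        return StackingClassifier(
            estimators=[
                ("logistic", _make_model("logistic", seed)),
                ("knn", _make_model("knn", seed)),
                ("tree", _make_model("tree_forward_pruned", seed)),
            ],
            final_estimator=LogisticRegression(max_iter=2000, random_state=seed),
            cv=3,
        )
    raise ClassifyError(f"unknown model {name!r}; choose from {MODELS}")


def _bootstrap_fold(
    idx: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap-resample a training fold, stratified so both classes survive."""
    out = []
    for cls in np.unique(y[idx]):
        cls_idx = idx[y[idx] == cls]
        out.append(rng.choice(cls_idx, size=cls_idx.size, replace=True))
    return np.concatenate(out)


def evaluate(
    features: pd.DataFrame,
    labels: np.ndarray,
    model: str = "logistic",
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    bootstrap: bool = True,
    selected: list[str] | None = None,
    positive_label: object = None,
) -> ClassifierReport:
    """Repeated stratified CV with bootstrap-resampled training folds.

    Out-of-fold probabilities are averaged per sample across repeats; the
    pooled predictions give the confusion matrix at a 0.5 cut and the AUC.
    """
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ClassifyError("binary labels required")
    if positive_label is None:
        positive_label = classes[-1]
    y = (y_raw == positive_label).astype(int)
    if y.size < 10:
        raise ClassifyError("need n >= 10 samples")
    if min(np.bincount(y)) < n_folds:
        raise ClassifyError("minority class smaller than fold count")

    X_all = features.copy()
    if selected is not None:
        X_all = X_all[selected]
    X_all = X_all.fillna(X_all.mean(numeric_only=True))
    X = X_all.to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    prob_sum = np.zeros(y.size)
    prob_count = np.zeros(y.size)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for train, test in skf.split(X, y):
            fit_idx = _bootstrap_fold(train, y, rng) if bootstrap else train
            clf = _make_model(model, seed + rep)
            clf.fit(X[fit_idx], y[fit_idx])
            prob = clf.predict_proba(X[test])[:, 1]
            prob_sum[test] += prob
            prob_count[test] += 1
    prob = prob_sum / prob_count
    pred = (prob >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    metrics = metrics_from_confusion(tp, fp, tn, fn)
    auc = float(roc_auc_score(y, prob))
    return ClassifierReport(
        model=model,
        selected_features=list(X_all.columns),
        cv_scheme=(
            f"stratified {n_folds}-fold x {n_repeats} repeats"
            + (", bootstrapped training folds" if bootstrap else "")
        ),
        seed=seed,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=auc,
        **metrics,
    )


def condensed_pepE_mode(
    features: pd.DataFrame, labels: np.ndarray, **kwargs
) -> ClassifierReport:
    """Single-peptide deployment mode: PepE absolute activity + inhibitor
    profile only, evaluated with the full protocol."""
    cols = [c for c in features.columns if str(c).startswith("PepE")]
    if not cols:
        raise ClassifyError("no PepE features present")
    report = evaluate(features[cols], labels, **kwargs)
    report.condensed_panel = True
    return report
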