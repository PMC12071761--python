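"""Stratified k-fold evaluation of preprocessing x extractor x classifier
combinations.

The protocol mirrors a balanced storage-time study: within each class the
samples are shuffled (seeded) and dealt into k near-equal parts; fold f
tests on part f and trains on the rest, so with 5 classes x 60 samples and
k = 5 every test fold holds 60 spectra (12 per class) and every training
fold 240.

For one combination, each fold independently fits the preprocessing chain
(including the MSC reference), the discriminant extractor, and the
classifier on its training part only; test predictions are pooled into a
single confusion matrix.  Reported metrics: per-fold and mean accuracy,
the sample (n-1) SD of the fold accuracies, and macro-averaged
precision/recall/F1 on the pooled confusion matrix (with balanced folds
macro recall coincides with pooled accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from nirdisc.boosting import BoostConfig, fit_boosted, predict_boosted
from nirdisc.cart import CartConfig, predict_tree, select_subtree_cv
from nirdisc.preprocess import PreprocessSpec, fit_apply_chain
from nirdisc.spectra import SpectraSet
from nirdisc.sss_lda import (
    ExtractorNotApplicableError,
    NoDiscriminantInformationError,
    fit_extractor,
    project,
)

__all__ = [
    "CVPlan",
    "MetricsReport",
    "stratified_kfold",
    "run_combo_cv",
    "grid_report",
    "grid_table",
]


@dataclass
class CVPlan:
    """Per-sample fold assignments for stratified k-fold CV."""

    n_folds: int
    assignments: np.ndarray
    stratified: bool
    seed: int


@dataclass
class MetricsReport:
    """Pooled evaluation of one preprocess-extractor-classifier combo."""

    combo_label: str
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    accuracy_sd: float  # sample (n-1) SD over fold accuracies
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # (K, K); rows true, columns predicted
    classes: np.ndarray
    error: Optional[str] = None  # set when the combo failed (e.g. CLDA n/a)
    fold_scores: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "combo_label": self.combo_label,
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "mean_accuracy": float(self.mean_accuracy),
            "accuracy_sd": float(self.accuracy_sd),
            "accuracy_sd_denominator": "sample (n-1) over folds",
            "macro_precision": float(self.macro_precision),
            "macro_recall": float(self.macro_recall),
            "macro_f1": float(self.macro_f1),
            "confusion": [[int(v) for v in row] for row in self.confusion],
            "classes": [str(c) for c in self.classes],
            "error": self.error,
        }


def stratified_kfold(labels, n_folds: int, seed: int) -> CVPlan:
    """Shuffle each class (seeded) and deal its samples into n_folds parts
    whose sizes differ by at most one."""
    labels = np.asarray(labels).astype(str)
    rng = np.random.default_rng(seed)
    assignments = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} samples but n_folds={n_folds}"
            )
        perm = rng.permutation(idx)
        assignments[perm] = np.arange(perm.size) % n_folds
    return CVPlan(n_folds=n_folds, assignments=assignments, stratified=True, seed=seed)


def _failed_report(label: str, classes: np.ndarray, n_folds: int, msg: str) -> MetricsReport:
    K = classes.size
    return MetricsReport(
        combo_label=label,
        per_fold_accuracy=np.full(n_folds, np.nan),
        mean_accuracy=float("nan"),
        accuracy_sd=float("nan"),
        macro_precision=float("nan"),
        macro_recall=float("nan"),
        macro_f1=float("nan"),
        confusion=np.zeros((K, K), dtype=int),
        classes=classes,
        error=msg,
    )


def _fit_predict_classifier(name, config, Ztr, ytr, Zte, seed_offset=0):
    if name.upper() == "CART":
        cfg = config or CartConfig()
        tree = select_subtree_cv(Ztr, ytr, cfg)
        return predict_tree(tree, Zte)
    if name.upper() == "BOOST":
        cfg = config or BoostConfig()
        model = fit_boosted(Ztr, ytr, cfg)
        return predict_boosted(model, Zte)[0]
    raise ValueError(f"unknown classifier {name!r}; valid: CART, BOOST")


def run_combo_cv(
    data: SpectraSet,
    preprocess: PreprocessSpec,
    extractor: str,
    classifier: str,
    plan: CVPlan,
    classifier_config=None,
    n_components: Optional[int] = None,
    rank_tolerance: Optional[float] = None,
) -> MetricsReport:
    """Evaluate one combination under the fold plan.

    Every fold refits preprocessing, extractor, and classifier on its
    training part only.  An extractor whose preconditions fail (e.g. CLDA
    on nonsingular data) yields a report with ``error`` set, not a crash.
    """
    labels = data.labels.astype(str)
    classes = np.unique(labels)
    label = f"{preprocess.name}-{extractor}-{classifier}"
    y_true_all: list = []
    y_pred_all: list = []
    fold_acc = np.zeros(plan.n_folds)
    fold_scores: list = []
    try:
        for f in range(plan.n_folds):
            te = plan.assignments == f
            tr = ~te
            train, test = data.select(tr), data.select(te)
            p_train, p_test, _ = fit_apply_chain(preprocess, train, test)
            model = fit_extractor(
                extractor, p_train.absorbance, p_train.labels,
                d=n_components, rank_tolerance=rank_tolerance,
            )
            Ztr = project(model, p_train.absorbance)
            Zte = project(model, p_test.absorbance)
            ytr = p_train.labels.astype(str)
            yte = p_test.labels.astype(str)
            pred = _fit_predict_classifier(classifier, classifier_config, Ztr, ytr, Zte)
            pred = np.asarray(pred).astype(str)
            fold_acc[f] = float(np.mean(pred == yte))
            y_true_all.append(yte)
            y_pred_all.append(pred)
            fold_scores.append(
                {"fold": f, "sample_ids": test.sample_ids, "labels": yte, "scores": Zte}
            )
    except (ExtractorNotApplicableError, NoDiscriminantInformationError) as exc:
        return _failed_report(label, classes, plan.n_folds, str(exc))

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    )
    return MetricsReport(
        combo_label=label,
        per_fold_accuracy=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        accuracy_sd=float(np.std(fold_acc, ddof=1)) if plan.n_folds > 1 else 0.0,
        macro_precision=float(prec),
        macro_recall=float(rec),
        macro_f1=float(f1),
        confusion=conf,
        classes=classes,
        fold_scores=fold_scores,
    )


def grid_report(
    data: SpectraSet,
    preprocess_list: Sequence[PreprocessSpec],
    extractor_list: Sequence[str],
    classifier_list: Sequence[str],
    plan: CVPlan,
    classifier_configs: Optional[dict] = None,
    n_components: Optional[int] = None,
) -> list[MetricsReport]:
    """One MetricsReport per preprocess x extractor x classifier combo.

    Preprocessed folds and fitted projections are cached across
    classifiers (they do not depend on the classifier), which leaves the
    per-combo results identical to independent :func:`run_combo_cv` calls.
    """
    classifier_configs = classifier_configs or {}
    labels = data.labels.astype(str)
    classes = np.unique(labels)
    reports: list[MetricsReport] = []

    for pp in preprocess_list:
        fold_data = []
        for f in range(plan.n_folds):
            te = plan.assignments == f
            train, test = data.select(~te), data.select(te)
            p_train, p_test, _ = fit_apply_chain(pp, train, test)
            fold_data.append((p_train, p_test))
        for ext in extractor_list:
            # project once per fold, reuse for every classifier
            projections = []
            ext_error = None
            try:
                for p_train, p_test in fold_data:
                    model = fit_extractor(
                        ext, p_train.absorbance, p_train.labels, d=n_components
                    )
                    projections.append(
                        (
                            project(model, p_train.absorbance),
                            p_train.labels.astype(str),
                            project(model, p_test.absorbance),
                            p_test.labels.astype(str),
                            p_test.sample_ids,
                        )
                    )
            except (ExtractorNotApplicableError, NoDiscriminantInformationError) as exc:
                ext_error = str(exc)
            for clf in classifier_list:
                label = f"{pp.name}-{ext}-{clf}"
                if ext_error is not None:
                    reports.append(
                        _failed_report(label, classes, plan.n_folds, ext_error)
                    )
                    continue
                fold_acc = np.zeros(plan.n_folds)
                yt_all, yp_all, fold_scores = [], [], []
                for f, (Ztr, ytr, Zte, yte, sids) in enumerate(projections):
                    pred = np.asarray(
                        _fit_predict_classifier(
                            clf, classifier_configs.get(clf.upper()), Ztr, ytr, Zte
                        )
                    ).astype(str)
                    fold_acc[f] = float(np.mean(pred == yte))
                    yt_all.append(yte)
                    yp_all.append(pred)
                    fold_scores.append(
                        {"fold": f, "sample_ids": sids, "labels": yte, "scores": Zte}
                    )
                y_true = np.concatenate(yt_all)
                y_pred = np.concatenate(yp_all)
                conf = confusion_matrix(y_true, y_pred, labels=classes)
                prec, rec, f1, _ = precision_recall_fscore_support(
                    y_true, y_pred, labels=classes, average="macro", zero_division=0
                )
                reports.append(
                    MetricsReport(
                        combo_label=label,
                        per_fold_accuracy=fold_acc,
                        mean_accuracy=float(fold_acc.mean()),
                        accuracy_sd=float(np.std(fold_acc, ddof=1))
                        if plan.n_folds > 1 else 0.0,
                        macro_precision=float(prec),
                        macro_recall=float(rec),
                        macro_f1=float(f1),
                        confusion=conf,
                        classes=classes,
                        fold_scores=fold_scores,
                    )
                )
    return reports


def grid_table(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Long-form table of the grid plus an average-accuracy row per
    preprocessing column (classifier-wise), mirroring the usual
    accuracy-grid presentation."""
    rows = []
    for r in reports:
        pp, ext, clf = r.combo_label.split("-")
        rows.append(
            {
                "preprocess": pp,
                "extractor": ext,
                "classifier": clf,
                "mean_accuracy": r.mean_accuracy,
                "accuracy_sd": r.accuracy_sd,
                "macro_precision": r.macro_precision,
                "macro_recall": r.macro_recall,
                "macro_f1": r.macro_f1,
                "error": r.error or "",
            }
        )
    frame = pd.DataFrame(rows)
    avg = (
        frame.groupby(["preprocess", "classifier"], sort=False)["mean_accuracy"]
        .mean()
        .reset_index()
    )
    avg["extractor"] = "Average"
    return pd.concat([frame, avg], ignore_index=True)
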