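"""Evaluation layer: linear regression with inference, repeated
single-hidden-layer neural-network classification, and the paired
with/without-model-features comparison.

Regression reports cross-validated and in-sample RMSE together with OLS
coefficient inference (statsmodels).  Classification repeats a 50-unit
MLP over independent stratified 70/30 splits and averages
confusion-matrix metrics (macro over classes, then over repetitions).
Both arms of a comparison always share the identical splits.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .enrich import tertile_discretize

__all__ = [
    "LinearReport",
    "ClassReport",
    "ComparisonReport",
    "fit_linear_report",
    "fit_nn_repeated",
    "confusion_metrics",
    "compare_enrichment",
    "compare_on_table",
    "default_tasks",
    "CLINICAL_FEATURES",
]

#: the covariate columns every synthetic cohort carries
CLINICAL_FEATURES = ("age", "bmi", "ethnicity", "laterality", "BRCA",
                     "TP53", "PIK3CA", "lymph_node", "obesity")


def default_tasks(n_timepoints: int = 4,
                  include_classification: bool = True) -> list[dict]:
    """The standard prediction tasks on a continuous cohort: later MRI
    volumes from clinical covariates plus earlier volumes."""
    clinical = list(CLINICAL_FEATURES)
    tasks = [
        {"kind": "regression", "target": "Volume2",
         "features": clinical + ["Volume1"]},
        {"kind": "regression", "target": "Volume3",
         "features": clinical + ["Volume1"]},
        {"kind": "regression", "target": "Volume3",
         "features": clinical + ["Volume1", "Volume2"]},
    ]
    if include_classification:
        tasks.append({"kind": "classification", "target": "Volume2",
                      "features": clinical + ["Volume1"]})
    return tasks


@dataclasses.dataclass
class LinearReport:
    target: str
    features: list[str]
    rmse_cv: float
    rmse_insample: float
    f_pvalue: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    significant: list[str]
    n: int
    dropped_collinear: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ClassReport:
    target: str
    features: list[str]
    n_reps: int
    mean: dict[str, float]   # accuracy / recall / precision / f1
    sd: dict[str, float]
    confusion_total: np.ndarray

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion_total"] = self.confusion_total.tolist()
        return d


@dataclasses.dataclass
class ComparisonReport:
    tasks: list[dict]

    def to_dict(self) -> dict:
        return {"tasks": self.tasks}


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop later columns until the design (with intercept) has
    full column rank."""
    dropped: list[str] = []
    cols = list(X.columns)
    def rank(c):
        M = np.column_stack([np.ones(len(X)), X[c].to_numpy(float)])
        return np.linalg.matrix_rank(M)
    while cols and rank(cols) < len(cols) + 1:
        # drop the last column whose removal restores rank
        for c in reversed(cols):
            rest = [x for x in cols if x != c]
            if rank(rest) == len(rest) + 1 or not rest:
                cols = rest
                dropped.append(c)
                break
        else:
            break
    return X[cols], dropped


def fit_linear_report(table: pd.DataFrame, target: str,
                      features: Sequence[str], cv: int = 5,
                      alpha: float = 0.05, seed: int = 0) -> LinearReport:
    """OLS with intercept: cross-validated and in-sample RMSE plus
    two-sided coefficient t-tests and the overall F-test.

    The cross-validated RMSE uses ``cv`` shuffled folds seeded by
    ``seed``; in-sample RMSE uses divisor n.  Collinear columns are
    dropped (rightmost first) with a warning and recorded in the report.
    """
    y = table[target].to_numpy(dtype=float)
    X = table[list(features)].astype(float)
    n = len(y)
    if n <= len(features) + 1:
        raise ValueError("need n > number of features + 1")
    X, dropped = _drop_collinear(X)
    if dropped:
        warnings.warn(f"dropped collinear feature(s): {dropped}")

    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    rmse_in = float(np.sqrt(np.mean(fit.resid ** 2)))

    Xa = Xc.to_numpy(dtype=float)
    preds = np.empty(n)
    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    for tr, te in kf.split(Xa):
        beta, *_ = np.linalg.lstsq(Xa[tr], y[tr], rcond=None)
        preds[te] = Xa[te] @ beta
    rmse_cv = float(np.sqrt(np.mean((preds - y) ** 2)))

    pvals = {k: float(v) for k, v in fit.pvalues.items() if k != "const"}
    coefs = {k: float(v) for k, v in fit.params.items() if k != "const"}
    return LinearReport(
        target=target, features=list(X.columns), rmse_cv=rmse_cv,
        rmse_insample=rmse_in, f_pvalue=float(fit.f_pvalue),
        coefficients=coefs, p_values=pvals,
        significant=[k for k, v in pvals.items() if v <= alpha],
        n=n, dropped_collinear=dropped)


def confusion_metrics(matrix, average: str = "macro"
                      ) -> tuple[float, float, float, float]:
    """(accuracy, recall, precision, F1) of a square confusion matrix.

    Rows are true classes, columns predictions.  Per-class scores are
    averaged (macro by default; micro pools counts); a class with zero
    support or zero predictions scores 0 on the undefined metric, with a
    warning.
    """
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0) or not np.issubdtype(M.dtype, np.number):
        raise ValueError("confusion matrix must be nonnegative")
    total = M.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(M).astype(float)
    accuracy = float(diag.sum() / total)
    support = M.sum(axis=1).astype(float)
    predicted = M.sum(axis=0).astype(float)
    if average == "micro":
        recall = precision = f1 = accuracy
        return accuracy, recall, precision, f1
    if np.any(support == 0):
        warnings.warn("class with zero support: its recall is set to 0")
    if np.any(predicted == 0):
        warnings.warn("class never predicted: its precision is set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        rec = np.where(support > 0, diag / np.maximum(support, 1e-300), 0.0)
        prec = np.where(predicted > 0, diag / np.maximum(predicted, 1e-300), 0.0)
        denom = rec + prec
        f1c = np.where(denom > 0, 2 * rec * prec / np.maximum(denom, 1e-300),
                       0.0)
    return accuracy, float(rec.mean()), float(prec.mean()), float(f1c.mean())


def fit_nn_repeated(table: pd.DataFrame, target_cat: str,
                    features: Sequence[str], hidden: int = 50,
                    reps: int = 100, test_size: float = 0.3,
                    seed: int = 0, average: str = "macro",
                    max_iter: int = 300) -> ClassReport:
    """Repeated one-hidden-layer MLP classification.

    Each repetition draws an independent stratified train/test split and
    weight initialization (both derived from ``seed``), standardizes
    features on the training fold, fits an MLP with ``hidden`` units
    (early stopping off, fixed ``max_iter``), and scores the held-out
    confusion matrix; metrics are averaged over repetitions.
    """
    y = table[target_cat].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("target must have at least 2 classes")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    X = table[list(features)].to_numpy(dtype=float)
    splitter = StratifiedShuffleSplit(n_splits=reps, test_size=test_size,
                                      random_state=seed)
    metrics = {k: [] for k in ("accuracy", "recall", "precision", "f1")}
    total = np.zeros((len(classes), len(classes)), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence at fixed max_iter
        for r, (tr, te) in enumerate(splitter.split(X, y)):
            scaler = StandardScaler().fit(X[tr])
            clf = MLPClassifier(hidden_layer_sizes=(hidden,),
                                max_iter=max_iter, early_stopping=False,
                                random_state=seed + r + 1)
            clf.fit(scaler.transform(X[tr]), y[tr])
            pred = clf.predict(scaler.transform(X[te]))
            M = _sk_confusion(y[te], pred, labels=classes)
            total += M
            acc, rec, prec, f1 = confusion_metrics(M, average=average)
            for k, v in zip(("accuracy", "recall", "precision", "f1"),
                            (acc, rec, prec, f1)):
                metrics[k].append(v)
    return ClassReport(
        target=target_cat, features=list(features), n_reps=reps,
        mean={k: float(np.mean(v)) for k, v in metrics.items()},
        sd={k: float(np.std(v)) for k, v in metrics.items()},
        confusion_total=total)


def compare_enrichment(cohort: pd.DataFrame, params, config, spec, schedule,
                       tasks: Sequence[Mapping], seed: int = 0,
                       cv: int = 5, reps: int = 100, hidden: int = 50,
                       ) -> ComparisonReport:
    """Enrich a continuous cohort and run each task with and without the
    model-derived feature columns, on identical splits."""
    from .enrich import enrich_continuous
    enriched = enrich_continuous(cohort, params, config, spec, schedule)
    return compare_on_table(enriched, tasks, spec.column_names(), seed=seed,
                            cv=cv, reps=reps, hidden=hidden)


def compare_on_table(enriched: pd.DataFrame, tasks: Sequence[Mapping],
                     model_feature_columns: Sequence[str],
                     seed: int = 0, cv: int = 5, reps: int = 100,
                     hidden: int = 50) -> ComparisonReport:
    """Run each task twice on identical splits: clinical columns only
    versus clinical + model-derived columns.

    Each task is a mapping with keys ``kind`` ("regression" or
    "classification"), ``target`` and ``features`` (the clinical feature
    list, excluding model columns).  Classification targets that are
    continuous volumes are tertile-coded first.  Split identity between
    arms is guaranteed by sharing the fold/repetition seeds.
    """
    model_cols = [c for c in model_feature_columns if c in enriched.columns]
    out = []
    for i, task in enumerate(tasks):
        kind = task["kind"]
        target = task["target"]
        feats = list(task["features"])
        task_seed = seed + 1000 * (i + 1)
        entry = {"kind": kind, "target": target, "features": feats,
                 "model_features": model_cols}
        if kind == "regression":
            rep0 = fit_linear_report(enriched, target, feats, cv=cv,
                                     seed=task_seed)
            rep1 = fit_linear_report(enriched, target, feats + model_cols,
                                     cv=cv, seed=task_seed)
            entry["without"] = rep0.to_dict()
            entry["with"] = rep1.to_dict()
            entry["delta"] = {"rmse_cv": rep1.rmse_cv - rep0.rmse_cv,
                              "rmse_insample": rep1.rmse_insample
                              - rep0.rmse_insample}
        elif kind == "classification":
            tbl = enriched.copy()
            tcol = target
            if tbl[target].dtype.kind == "f":
                tcol = f"{target}_tertile"
                tbl[tcol] = tertile_discretize(tbl[target].to_numpy())
            rep0 = fit_nn_repeated(tbl, tcol, feats, hidden=hidden,
                                   reps=reps, seed=task_seed)
            rep1 = fit_nn_repeated(tbl, tcol, feats + model_cols,
                                   hidden=hidden, reps=reps, seed=task_seed)
            entry["without"] = rep0.to_dict()
            entry["with"] = rep1.to_dict()
            entry["delta"] = {k: rep1.mean[k] - rep0.mean[k]
                              for k in rep1.mean}
        else:
            raise ValueError(f"unknown task kind {kind!r}")
        out.append(entry)
    return ComparisonReport(tasks=out)
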