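"""Classifiers for variant-activity prediction and their evaluation.

Four algorithm families — random forest (RF), RBF-kernel support vector
machine (SVM), bagged decision trees (DT), and a two-hidden-layer neural
network (NN) — are trained on the 27-attribute variant feature vectors to
separate unaffected (U) from detrimentally affected (A) variants. The
positive class is U throughout. Evaluation covers deterministic LOOCV,
repeated stratified 10-fold CV, label-permutation significance, and
learning curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import (LeaveOneOut, StratifiedKFold,
                                     StratifiedShuffleSplit, cross_val_predict)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import CATEGORICAL_COLUMNS, FEATURE_COLUMNS, NUMERIC_COLUMNS, PAD_AA
from .structure_io import AMINO_ACIDS

ALGORITHMS = ("RF", "SVM", "DT", "NN")

_AA_CATEGORIES = list(AMINO_ACIDS)
_CATEGORY_MAP = {
    "native": _AA_CATEGORIES,
    "replacement": _AA_CATEGORIES,
    **{f"aa_n{k}": _AA_CATEGORIES + [PAD_AA] for k in range(1, 7)},
    "secondary_structure": ["H", "S", "C"],
    "depth": ["S", "U", "B"],
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus the hyperparameters recorded with every result.

    Defaults: RF with 100 trees; SVM with C = 2.0, RBF gamma = 0.01,
    standardized inputs and Platt-calibrated probabilities; DT as 10 bagged
    trees; NN with two hidden layers of (27 + 2) / 2 ≈ 14 units, SGD with
    learning rate 0.3 and momentum 0.2 for 500 epochs.
    """

    algorithm: str = "RF"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")

    def describe(self) -> dict:
        return {"algorithm": self.algorithm, "seed": self.seed,
                "params": dict(self.params)}


def _preprocessor(standardize: bool) -> ColumnTransformer:
    cat_cols = list(CATEGORICAL_COLUMNS)
    num_cols = list(NUMERIC_COLUMNS)
    encoder = OneHotEncoder(
        categories=[_CATEGORY_MAP[c] for c in cat_cols],
        handle_unknown="ignore")
    numeric = StandardScaler() if standardize else "passthrough"
    return ColumnTransformer([
        ("categorical", encoder, cat_cols),
        ("numeric", numeric, num_cols)])


def build_estimator(spec: ClassifierSpec) -> Pipeline:
    """An sklearn pipeline (encoding + classifier) for one spec."""
    algo, seed, p = spec.algorithm, spec.seed, spec.params
    if algo == "RF":
        clf = RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100), random_state=seed)
        standardize = False
    elif algo == "SVM":
        # sigmoid calibration = Platt's logistic fit to the decision values
        clf = CalibratedClassifierCV(
            SVC(C=p.get("C", 2.0), kernel="rbf", gamma=p.get("gamma", 0.01),
                random_state=seed),
            method="sigmoid", ensemble=False)
        standardize = True
    elif algo == "DT":
        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=p.get("n_estimators", 10), random_state=seed)
        standardize = False
    else:  # NN
        hidden = p.get("hidden_layer_sizes")
        if hidden is None:
            width = (len(FEATURE_COLUMNS) + 2) // 2
            hidden = (width, width)
        clf = MLPClassifier(hidden_layer_sizes=hidden, solver="sgd",
                            learning_rate_init=p.get("learning_rate", 0.3),
                            momentum=p.get("momentum", 0.2),
                            max_iter=p.get("epochs", 500),
                            random_state=seed)
        standardize = True
    return Pipeline([("encode", _preprocessor(standardize)), ("clf", clf)])


def _split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    if "activity" not in table.columns:
        raise ValueError("feature table lacks the 'activity' label column")
    y = table["activity"].to_numpy()
    bad = set(y) - {"U", "A"}
    if bad:
        raise ValueError(f"labels must be U/A, found {sorted(bad)}")
    return table[list(FEATURE_COLUMNS)], y


def train_classifier(table: pd.DataFrame, spec: ClassifierSpec) -> Pipeline:
    """Fit one classifier on a labeled feature table."""
    X, y = _split_xy(table)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    model = build_estimator(spec)
    model.fit(X, y)
    return model


def rank_auc(labels: Sequence[str], scores_u: Sequence[float]) -> float:
    """AUC by the Mann–Whitney rank formulation with midranks for ties.

    ``scores_u`` are class-U probabilities (or any monotone score).
    """
    y = np.asarray(labels)
    s = np.asarray(scores_u, dtype=float)
    n_pos = int((y == "U").sum())
    n_neg = int((y == "A").sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    r_pos = ranks[y == "U"].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    bar: float
    mcc: float
    auc: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "tn", "fp", "fn", "sensitivity", "specificity",
                 "ppv", "bar", "mcc", "auc")}


def compute_metrics(labels: Sequence[str], predictions: Sequence[str],
                    scores_u: Sequence[float] | None = None) -> MetricsReport:
    """Confusion-matrix metrics with P = class U, N = class A.

    Undefined ratios (zero denominators) are reported as 0.0. AUC is NaN
    when no scores are supplied or a class is absent.
    """
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    tp = int(((y == "U") & (yhat == "U")).sum())
    tn = int(((y == "A") & (yhat == "A")).sum())
    fp = int(((y == "A") & (yhat == "U")).sum())
    fn = int(((y == "U") & (yhat == "A")).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    denom = math.sqrt(float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    auc = rank_auc(y, scores_u) if scores_u is not None else float("nan")
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens,
                         specificity=spec, ppv=ppv,
                         bar=0.5 * (sens + spec), mcc=mcc, auc=auc)


@dataclass(frozen=True)
class CVResult:
    scheme: str
    spec: ClassifierSpec
    metrics: MetricsReport              # aggregate (mean over repeats for k-fold)
    predictions: pd.DataFrame | None    # per-instance, LOOCV/single-repeat only
    per_repeat: tuple[MetricsReport, ...] = ()
    seeds: tuple[int, ...] = ()


def _predict_cv(table: pd.DataFrame, spec: ClassifierSpec,
                cv) -> tuple[np.ndarray, np.ndarray]:
    X, y = _split_xy(table)
    model = build_estimator(spec)
    try:
        proba = cross_val_predict(model, X, y, cv=cv, method="predict_proba")
    except ValueError as exc:
        raise ValueError(
            f"cross-validation split failed (a fold may lack a class): {exc}"
        ) from exc
    classes = sorted(set(y))  # ['A', 'U']
    u_col = classes.index("U")
    scores_u = proba[:, u_col]
    yhat = np.where(scores_u >= 0.5, "U", "A")
    return yhat, scores_u


def cross_validate(table: pd.DataFrame, spec: ClassifierSpec,
                   scheme: str = "loocv", n_repeats: int = 10,
                   seed: int | None = None) -> CVResult:
    """LOOCV or repeated stratified 10-fold CV on a labeled feature table.

    LOOCV is deterministic given the model seed. 10-fold results are the
    mean over ``n_repeats`` independent stratifications whose seeds are
    recorded in the result.
    """
    X, y = _split_xy(table)
    if seed is None:
        seed = spec.seed
    if scheme == "loocv":
        yhat, scores_u = _predict_cv(table, spec, LeaveOneOut())
        metrics = compute_metrics(y, yhat, scores_u)
        preds = pd.DataFrame({"activity": y, "predicted": yhat,
                              "score_u": scores_u})
        return CVResult(scheme="loocv", spec=spec, metrics=metrics,
                        predictions=preds)
    if scheme != "10fold":
        raise ValueError("scheme must be 'loocv' or '10fold'")
    reports = []
    seeds = tuple(seed + r for r in range(n_repeats))
    preds = None
    for s in seeds:
        cv = StratifiedKFold(n_splits=10, shuffle=True, random_state=s)
        yhat, scores_u = _predict_cv(table, spec, cv)
        reports.append(compute_metrics(y, yhat, scores_u))
        if n_repeats == 1:
            preds = pd.DataFrame({"activity": y, "predicted": yhat,
                                  "score_u": scores_u})
    mean = _mean_metrics(reports)
    return CVResult(scheme="10fold", spec=spec, metrics=mean,
                    predictions=preds, per_repeat=tuple(reports), seeds=seeds)


def _mean_metrics(reports: Sequence[MetricsReport]) -> MetricsReport:
    def m(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in reports]))

    return MetricsReport(
        tp=round(m("tp")), tn=round(m("tn")), fp=round(m("fp")),
        fn=round(m("fn")), sensitivity=m("sensitivity"),
        specificity=m("specificity"), ppv=m("ppv"), bar=m("bar"),
        mcc=m("mcc"), auc=m("auc"))


@dataclass(frozen=True)
class PermutationResult:
    observed: MetricsReport
    null_bar: np.ndarray
    null_mcc: np.ndarray
    p_bar: float
    p_mcc: float
    seed: int
    scheme: str

    @property
    def summary(self) -> dict:
        return {
            "bar_mean": float(self.null_bar.mean()),
            "bar_sd": float(self.null_bar.std(ddof=1)),
            "mcc_mean": float(self.null_mcc.mean()),
            "mcc_sd": float(self.null_mcc.std(ddof=1)),
            "p_bar": self.p_bar, "p_mcc": self.p_mcc,
        }


def permutation_significance(table: pd.DataFrame, spec: ClassifierSpec,
                             n_permutations: int, seed: int = 0,
                             scheme: str = "10fold") -> PermutationResult:
    """Null distribution of (BAR, MCC) under random label shuffles.

    Each permutation shuffles the U/A labels, reruns cross-validation, and
    records BAR and MCC; the empirical p-value for the unpermuted result is
    (1 + #{null ≥ observed}) / (n + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be ≥ 1")
    observed = cross_validate(table, spec, scheme=scheme, n_repeats=1,
                              seed=seed).metrics
    rng = np.random.default_rng(seed)
    bars, mccs = [], []
    labels = table["activity"].to_numpy()
    for k in range(n_permutations):
        shuffled = table.copy()
        shuffled["activity"] = rng.permutation(labels)
        res = cross_validate(shuffled, spec, scheme=scheme, n_repeats=1,
                             seed=seed + k + 1)
        bars.append(res.metrics.bar)
        mccs.append(res.metrics.mcc)
    null_bar = np.array(bars)
    null_mcc = np.array(mccs)
    p_bar = (1 + int((null_bar >= observed.bar).sum())) / (n_permutations + 1)
    p_mcc = (1 + int((null_mcc >= observed.mcc).sum())) / (n_permutations + 1)
    return PermutationResult(observed=observed, null_bar=null_bar,
                             null_mcc=null_mcc, p_bar=p_bar, p_mcc=p_mcc,
                             seed=seed, scheme=scheme)


def learning_curve(table: pd.DataFrame, spec: ClassifierSpec,
                   sizes: Sequence[int], samples_per_size: int = 10,
                   seed: int = 0) -> pd.DataFrame:
    """Mean ± sd of (BAR, MCC, AUC) from 10-fold CV at growing subset sizes.

    At each size, ``samples_per_size`` stratified random subsets are drawn
    without replacement; a size equal to the full table reduces to repeated
    10-fold CV on the whole set.
    """
    n = len(table)
    rows = []
    for size in sizes:
        if size > n:
            raise ValueError(f"size {size} exceeds dataset size {n}")
        reports = []
        if size == n:
            res = cross_validate(table, spec, scheme="10fold",
                                 n_repeats=samples_per_size, seed=seed)
            reports = list(res.per_repeat)
        else:
            splitter = StratifiedShuffleSplit(
                n_splits=samples_per_size, train_size=size, random_state=seed)
            X = table[list(FEATURE_COLUMNS)]
            y = table["activity"]
            for k, (idx, _) in enumerate(splitter.split(X, y)):
                sub = table.iloc[idx].reset_index(drop=True)
                res = cross_validate(sub, spec, scheme="10fold", n_repeats=1,
                                     seed=seed + k)
                reports.append(res.metrics)
        for stat in ("bar", "mcc", "auc"):
            vals = np.array([getattr(r, stat) for r in reports])
            rows.append({"size": size, "metric": stat,
                         "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                         "n_samples": len(vals)})
    return pd.DataFrame(rows)
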