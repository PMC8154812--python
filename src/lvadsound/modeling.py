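"""Filter + wrapper feature selection and the multi-classifier benchmark.

The selection procedure screens the 19 acoustic features with per-feature
statistics (unpaired t-test p-values; random-forest Gini importance), then

1. filter stage: features are added in rank order while the leave-one-out
   misclassification error of a discriminant-analysis classifier is
   recorded; the retained subset is the earliest prefix reaching the
   minimum error;
2. wrapper stage: greedy forward sequential selection inside the filter
   subset, scored by the same LOOCV error, stopping when no addition
   improves it.

The benchmark trains nine classifiers (discriminant analysis, k-nearest
neighbour with k = 5 distance weighting, Gaussian and kernel naive Bayes,
random forest, linear and RBF support vector machines, decision tree, and a
bagged-tree ensemble) on a stratified 75/25 split, with hyper-parameters
tuned on the training portion only (LOOCV, except tenfold stratified CV for
the forest/ensemble) and reports accuracy, AUC, true positive rate and true
negative rate on the untouched test set.  The positive class is "significant
aortic regurgitation present".

All imputation, scaling and tuning is fitted on training data only — the
class imbalance (~10% positives) makes leakage especially flattering, so the
pipeline is built to make it impossible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import ttest_ind
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import (GridSearchCV, LeaveOneOut, StratifiedKFold,
                                     train_test_split)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .acoustic_features import FEATURE_NAMES
from .errors import ParameterError

logger = logging.getLogger(__name__)

LABEL_COLUMN = "ar_label"


def _feature_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c in FEATURE_NAMES]
    if not cols:  # non-catalogue tables (simulations) still work
        cols = [c for c in table.columns
                if c not in (LABEL_COLUMN, "recording_id")]
    return cols


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ParameterError(LABEL_COLUMN, "table contains a single class")


# --------------------------------------------------------------------------
# rankings
# --------------------------------------------------------------------------

def rank_by_ttest(table: pd.DataFrame) -> list[str]:
    """Features ordered by ascending unpaired t-test p-value (AR+ vs AR-).

    Ties (including all-NaN p-values) are broken by catalogue order — the
    stable sort keeps the input column order for equal keys.
    """
    cols = _feature_columns(table)
    y = table[LABEL_COLUMN].to_numpy()
    _check_two_classes(y)
    pvals = []
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        a, b = v[(y == 0) & np.isfinite(v)], v[(y == 1) & np.isfinite(v)]
        if a.size < 2 or b.size < 2:
            pvals.append(np.inf)
            continue
        with np.errstate(all="ignore"):
            p = ttest_ind(a, b, equal_var=True).pvalue
        pvals.append(p if np.isfinite(p) else 1.0)
    order = np.argsort(pvals, kind="stable")
    return [cols[i] for i in order]


def rank_by_gini(table: pd.DataFrame, seed: int = 0,
                 n_estimators: int = 300) -> list[str]:
    """Features ordered by descending random-forest mean impurity decrease."""
    cols = _feature_columns(table)
    y = table[LABEL_COLUMN].to_numpy()
    _check_two_classes(y)
    X = SimpleImputer(strategy="median").fit_transform(
        table[cols].to_numpy(dtype=float))
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(X, y)
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return [cols[i] for i in order]


def rank_by_nca(table: pd.DataFrame, seed: int = 0
                ) -> tuple[list[str], np.ndarray]:
    """Neighbourhood-component-analysis feature weights, descending.

    Optional third ranking route; returns (ranking, per-feature weights).
    Non-convergence is logged, not raised.
    """
    from sklearn.neighbors import NeighborhoodComponentsAnalysis

    cols = _feature_columns(table)
    y = table[LABEL_COLUMN].to_numpy()
    _check_two_classes(y)
    X = SimpleImputer(strategy="median").fit_transform(
        table[cols].to_numpy(dtype=float))
    X = StandardScaler().fit_transform(X)
    nca = NeighborhoodComponentsAnalysis(random_state=seed, max_iter=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            nca.fit(X, y)
        except Exception as exc:  # pragma: no cover - solver failure path
            logger.warning("NCA did not converge: %s", exc)
            raise
    weights = np.linalg.norm(nca.components_, axis=0)
    order = np.argsort(-weights, kind="stable")
    return [cols[i] for i in order], weights


# --------------------------------------------------------------------------
# LOOCV discriminant-analysis error (the selection criterion)
# --------------------------------------------------------------------------

def _fit_lda(Xtr: np.ndarray, ytr: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            lda.fit(Xtr, ytr)
        except (np.linalg.LinAlgError, IndexError, ValueError):
            # zero within-class variance / singular covariance
            logger.info("degenerate within-class covariance; refitting with "
                        "shrinkage regularization")
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(Xtr, ytr)
    return lda


def loo_misclassification(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out misclassification error of discriminant analysis.

    Median imputation is refitted inside every fold (training rows only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    wrong = 0
    has_nan = np.isnan(X).any()
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, Xte = X[tr], X[~tr]
        if has_nan:
            med = np.nanmedian(Xtr, axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            Xtr = np.where(np.isnan(Xtr), med, Xtr)
            Xte = np.where(np.isnan(Xte), med, Xte)
        if np.unique(y[tr]).size < 2:
            wrong += 1
            continue
        lda = _fit_lda(Xtr, y[tr])
        wrong += int(lda.predict(Xte)[0] != y[i])
    return wrong / n


# --------------------------------------------------------------------------
# filter + wrapper selection
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    ttest_ranking: list
    gini_ranking: list
    ranking_used: str
    filter_trace: list           # LOOCV error after each rank-order addition
    filter_subset: list
    wrapper_trace: list          # error after each greedy addition
    wrapper_subset: list
    cv_scheme: str = "leave-one-out, discriminant analysis"

    def trace_frame(self) -> pd.DataFrame:
        ranking = (self.ttest_ranking if self.ranking_used == "ttest"
                   else self.gini_ranking)
        return pd.DataFrame({
            "step": np.arange(1, len(self.filter_trace) + 1),
            "feature_added": ranking[:len(self.filter_trace)],
            "loocv_error": self.filter_trace,
        })

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def filter_select(table: pd.DataFrame, ranking: list[str]
                  ) -> tuple[list[str], list[float]]:
    """Prefix of the ranking minimizing LOOCV discriminant error.

    Returns (subset, trace); on ties the earliest (smallest) prefix wins.
    """
    y = table[LABEL_COLUMN].to_numpy()
    _check_two_classes(y)
    trace = []
    for k in range(1, len(ranking) + 1):
        X = table[ranking[:k]].to_numpy(dtype=float)
        trace.append(loo_misclassification(X, y))
    best = int(np.argmin(trace))  # argmin returns the first minimum
    return ranking[:best + 1], trace


def wrapper_select(table: pd.DataFrame, filter_subset: list[str]
                   ) -> tuple[list[str], list[float]]:
    """Greedy forward sequential selection within the filter subset.

    Stops when no single addition lowers the LOOCV error.  If the greedy
    path somehow ends worse than the full filter subset, the filter subset
    is returned (the wrapper never worsens the selection).
    """
    if not filter_subset:
        raise ParameterError("filter_subset", "must be non-empty")
    y = table[LABEL_COLUMN].to_numpy()
    chosen: list[str] = []
    trace: list[float] = []
    best_err = np.inf
    while True:
        candidates = [c for c in filter_subset if c not in chosen]
        if not candidates:
            break
        errs = [loo_misclassification(
            table[chosen + [c]].to_numpy(dtype=float), y) for c in candidates]
        j = int(np.argmin(errs))  # ties -> first, i.e. filter-rank order
        if errs[j] < best_err:
            chosen.append(candidates[j])
            trace.append(errs[j])
            best_err = errs[j]
        else:
            break
    full_err = loo_misclassification(
        table[filter_subset].to_numpy(dtype=float), y)
    if not chosen or best_err > full_err:
        logger.info("greedy wrapper (err %.3f) did not beat the filter subset "
                    "(err %.3f); keeping the filter subset", best_err, full_err)
        return list(filter_subset), trace
    return chosen, trace


def select_features(table: pd.DataFrame, ranking_method: str = "ttest",
                    seed: int = 0) -> SelectionResult:
    """Run the full filter + wrapper procedure and keep full provenance."""
    ttest_ranking = rank_by_ttest(table)
    gini_ranking = rank_by_gini(table, seed=seed)
    ranking = {"ttest": ttest_ranking, "gini": gini_ranking}.get(ranking_method)
    if ranking is None:
        raise ParameterError("ranking_method", "must be 'ttest' or 'gini'")
    filter_subset, filter_trace = filter_select(table, ranking)
    wrapper_subset, wrapper_trace = wrapper_select(table, filter_subset)
    return SelectionResult(ttest_ranking=ttest_ranking,
                           gini_ranking=gini_ranking,
                           ranking_used=ranking_method,
                           filter_trace=filter_trace,
                           filter_subset=filter_subset,
                           wrapper_trace=wrapper_trace,
                           wrapper_subset=wrapper_subset)


# --------------------------------------------------------------------------
# kernel naive Bayes
# --------------------------------------------------------------------------

class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel-density class-conditionals.

    Bandwidths follow Silverman's rule per class and feature, scaled by
    ``bandwidth_factor``.  Degenerate (zero-spread) features fall back to a
    small floor bandwidth instead of a delta spike.
    """

    def __init__(self, bandwidth_factor: float = 1.0):
        self.bandwidth_factor = bandwidth_factor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self.train_ = []
        self.bandwidths_ = []
        for c in self.classes_:
            Xc = X[y == c]
            n = Xc.shape[0]
            sd = Xc.std(axis=0, ddof=1) if n > 1 else np.ones(Xc.shape[1])
            iqr = np.subtract(*np.percentile(Xc, [75, 25], axis=0))
            spread = np.minimum(sd, iqr / 1.34, where=iqr > 0, out=sd.copy())
            h = 0.9 * spread * n ** (-0.2) * self.bandwidth_factor
            h = np.where(h > 0, h, 1e-3 * (np.abs(Xc).mean(axis=0) + 1.0))
            self.train_.append(Xc)
            self.bandwidths_.append(h)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((X.shape[0], self.classes_.size))
        for ci in range(self.classes_.size):
            Xc, h = self.train_[ci], self.bandwidths_[ci]
            total = np.log(self.priors_[ci]) * np.ones(X.shape[0])
            for j in range(X.shape[1]):
                z = (X[:, j, None] - Xc[None, :, j]) / h[j]
                logk = -0.5 * z * z - 0.5 * np.log(2 * np.pi) - np.log(h[j])
                total += logsumexp(logk, axis=1) - np.log(Xc.shape[0])
            jll[:, ci] = total
        return jll

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        jll = self._joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


# --------------------------------------------------------------------------
# metrics and benchmark
# --------------------------------------------------------------------------

def evaluate_metrics(predictions, scores, labels) -> dict:
    """Accuracy, AUC (rank statistic), TPR and TNR (positive = AR present).

    Constant scores yield AUC 0.5 by the rank-tie convention.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels)
    pred = np.asarray(predictions)
    s = np.asarray(scores, dtype=float)
    if not (y.size == pred.size == s.size):
        raise ParameterError("predictions", "inputs must be aligned")
    acc = float((pred == y).mean())
    if np.unique(y).size < 2:
        auc = np.nan
    else:
        auc = float(roc_auc_score(y, s))
    pos, neg = y == 1, y == 0
    tpr = float((pred[pos] == 1).mean()) if pos.any() else np.nan
    tnr = float((pred[neg] == 0).mean()) if neg.any() else np.nan
    return {"accuracy": acc, "auc": auc, "tpr": tpr, "tnr": tnr}


@dataclass
class ModelReport:
    results: dict                 # classifier name -> metrics dict
    feature_subset: list
    split: str
    split_seed: int
    tuned: bool
    best_params: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"Classifier": name,
                 "Accuracy": m["accuracy"], "AUC": m["auc"],
                 "TPR": m["tpr"], "TNR": m["tnr"]}
                for name, m in self.results.items()]
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _classifier_specs(seed: int, tune: bool):
    """(name, estimator, grid, cv scheme) for the nine benchmark algorithms."""
    loo = LeaveOneOut()
    tenfold = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    return [
        ("discriminant_analysis", LinearDiscriminantAnalysis(), {}, None),
        ("knn", KNeighborsClassifier(n_neighbors=5, weights="distance"), {}, None),
        ("naive_bayes", GaussianNB(), {}, None),
        ("kernel_naive_bayes", KernelNaiveBayes(),
         {"clf__bandwidth_factor": [0.5, 1.0, 2.0]} if tune else {}, loo),
        ("random_forest", RandomForestClassifier(n_estimators=100, random_state=seed),
         {"clf__max_features": ["sqrt", None]} if tune else {}, tenfold),
        ("svm", SVC(kernel="linear", C=1.0),
         {"clf__C": [0.1, 1.0, 10.0]} if tune else {}, loo),
        ("kernel_svm", SVC(kernel="rbf", gamma="scale"),
         {"clf__C": [1.0, 10.0]} if tune else {}, loo),
        ("decision_tree", DecisionTreeClassifier(random_state=seed),
         {"clf__max_depth": [2, 4, None]} if tune else {}, loo),
        ("ensemble", BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=100, random_state=seed),
         {"clf__max_samples": [0.8, 1.0]} if tune else {}, tenfold),
    ]


def benchmark_classifiers(table: pd.DataFrame, feature_subset: list[str],
                          split_seed: int = 0, tune: bool = True,
                          test_size: float = 0.25,
                          algorithms: list[str] | None = None) -> ModelReport:
    """Train and evaluate the benchmark classifiers on a stratified 75/25 split.

    Tuning (when enabled) searches small grids with the scheme noted in
    :func:`_classifier_specs`, scored by misclassification, on the training
    portion only.  A split leaving either class empty (possible only at tiny
    n) is redrawn with a logged note.  ``algorithms`` restricts the run to a
    named subset (default: all nine).
    """
    if not feature_subset:
        raise ParameterError("feature_subset", "must be non-empty")
    y = table[LABEL_COLUMN].to_numpy()
    _check_two_classes(y)
    X = table[list(feature_subset)].to_numpy(dtype=float)

    seed = split_seed
    for attempt in range(10):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=seed)
        if np.unique(ytr).size == 2 and np.unique(yte).size == 2:
            break
        logger.warning("split seed %d left a class empty; redrawing", seed)
        seed += 1
    else:  # pragma: no cover - stratification prevents this
        raise ParameterError("split_seed", "could not produce a two-class split")

    results, best_params = {}, {}
    specs = _classifier_specs(seed, tune)
    if algorithms is not None:
        known = {name for name, *_ in specs}
        bad = set(algorithms) - known
        if bad:
            raise ParameterError("algorithms", f"unknown: {sorted(bad)}")
        specs = [s for s in specs if s[0] in algorithms]
    for name, est, grid, cv in specs:
        pipe = Pipeline([("impute", SimpleImputer(strategy="median")),
                         ("scale", StandardScaler()),
                         ("clf", est)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if tune and grid:
                search = GridSearchCV(pipe, grid, scoring="accuracy", cv=cv,
                                      n_jobs=None)
                search.fit(Xtr, ytr)
                model = search.best_estimator_
                best_params[name] = {k.removeprefix("clf__"): v
                                     for k, v in search.best_params_.items()}
            else:
                model = clone(pipe)
                model.fit(Xtr, ytr)
            pred = model.predict(Xte)
            if hasattr(model, "predict_proba"):
                scores = model.predict_proba(Xte)[:, 1]
            else:
                scores = model.decision_function(Xte)
        results[name] = evaluate_metrics(pred, scores, yte)

    split_desc = (f"stratified {int((1 - test_size) * 100)}/"
                  f"{int(test_size * 100)}, n_train={ytr.size}, n_test={yte.size}")
    return ModelReport(results=results, feature_subset=list(feature_subset),
                       split=split_desc, split_seed=seed, tuned=tune,
                       best_params=best_params)
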