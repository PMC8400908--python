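"""Repeated stratified cross-validated AUROC model comparison.

Five learners are compared on the analysis table: plain multivariable
logistic regression, elastic-net-penalized logistic regression, random
forest, and support-vector classifiers with linear and RBF kernels.  Each
of the (default ten) repeats draws a fresh stratified k-fold split; within
each training fold hyperparameters are tuned by an inner 3-fold grid
search (AUROC scoring), the tuned model is fit on the training fold and
scored on the held-out fold, and the repeat-level AUROC is the mean over
folds.  The 95% CI is the normal approximation across repeat means.
Margin classifiers are scored by decision-function value (rank-equivalent
to a probability, so the AUROC does not depend on calibration).

Fold assignments are a deterministic function of the seed alone, so
results for different model specifications under one seed are paired on
identical splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import pairwise_distances, roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "MODEL_SPECS",
    "CVResult",
    "make_folds",
    "default_grid",
    "repeated_cv_auroc",
    "compare_models",
]

MODEL_SPECS = ("logistic", "elastic_net", "random_forest", "svm_linear", "svm_rbf")


@dataclass
class CVResult:
    model_name: str
    repeat_aurocs: np.ndarray      # one mean-over-folds value per repeat
    mean_auroc: float
    ci95: tuple
    seeds: list                    # per-repeat fold seeds
    k: int
    chosen_params: list            # per repeat: list of per-fold best params
    flagged_repeats: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.repeat_aurocs = np.asarray(self.repeat_aurocs, dtype=float)
        if ((self.repeat_aurocs < 0) | (self.repeat_aurocs > 1)).any():
            raise ValueError("AUROC values must lie in [0, 1]")
        if not (self.ci95[0] <= self.mean_auroc <= self.ci95[1]):
            raise ValueError("CI must bracket the mean")


def make_folds(y: np.ndarray, k: int = 5, stratified: bool = True,
               seed: int = 0) -> np.ndarray:
    """Fold label per subject; stratified folds keep per-fold class
    proportions within one subject of the global split.  Deterministic per
    seed.  Leave-one-out (k = n) is supported unstratified."""
    y = np.asarray(y, dtype=int)
    if stratified:
        counts = np.bincount(y)
        if counts.min() < k:
            raise ValueError(
                f"smallest class has {counts.min()} members < k={k}; "
                "use a smaller k or stratified=False"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        if k > len(y):
            raise ValueError("k cannot exceed the number of subjects")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test] = f
    return folds


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d = pairwise_distances(X)
    med = np.median(d[np.triu_indices_from(d, k=1)])
    return 1.0 / (2 * med**2) if med > 0 else 1.0


def default_grid(model_name: str, X: np.ndarray) -> dict:
    """Conventional hyperparameter grids (the motivating analysis states
    none): elastic-net mixing 0.1..1.0 by 0.1 x log C grid; RF
    features-per-split {sqrt(p), p/3}; SVM cost 2^-5..2^5, RBF width a
    median-heuristic bracket."""
    if model_name == "logistic":
        return {}
    if model_name == "elastic_net":
        return {"l1_ratio": [round(0.1 * i, 1) for i in range(1, 11)],
                "C": list(np.logspace(-2, 2, 5))}
    if model_name == "random_forest":
        p = X.shape[1]
        return {"max_features": ["sqrt", max(1, p // 3)]}
    if model_name == "svm_linear":
        return {"C": list(2.0 ** np.arange(-5, 6))}
    if model_name == "svm_rbf":
        g = _median_heuristic_gamma(X)
        return {"C": list(2.0 ** np.arange(-5, 6)),
                "gamma": [g / 10, g, g * 10]}
    raise ValueError(f"unknown model spec {model_name!r}; one of {MODEL_SPECS}")


def _build_estimator(model_name: str, seed: int):
    if model_name == "logistic":
        return LogisticRegression(C=np.inf, max_iter=2000)
    if model_name == "elastic_net":
        return LogisticRegression(solver="saga", l1_ratio=0.5, max_iter=5000)
    if model_name == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if model_name == "svm_linear":
        return SVC(kernel="linear")
    if model_name == "svm_rbf":
        return SVC(kernel="rbf")
    raise ValueError(f"unknown model spec {model_name!r}; one of {MODEL_SPECS}")


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def repeated_cv_auroc(model_name: str, X, y, k: int = 5, repeats: int = 10,
                      seed: int = 0, param_grid: Mapping | None = None,
                      inner_k: int = 3,
                      estimator_kwargs: Mapping | None = None) -> CVResult:
    """Repeated stratified k-fold AUROC for one model specification.

    Per repeat a fresh fold split is drawn (repeat-level seed = seed +
    repeat index); per outer fold the grid is tuned by inner ``inner_k``-
    fold cross-validation on the training data only.  A learner that fails
    on a fold skips that fold and flags the repeat.
    """
    X = np.asarray(pd.DataFrame(X), dtype=float)
    y = np.asarray(y, dtype=int)
    if param_grid is None:
        param_grid = default_grid(model_name, X)
    repeat_means = []
    seeds = []
    chosen = []
    flagged = []
    for rep in range(repeats):
        rep_seed = int(seed) + rep
        seeds.append(rep_seed)
        folds = make_folds(y, k=k, stratified=True, seed=rep_seed)
        fold_aurocs = []
        fold_params = []
        for f in range(k):
            train, test = folds != f, folds == f
            est = _build_estimator(model_name, rep_seed)
            if estimator_kwargs:
                est.set_params(**estimator_kwargs)
            try:
                if param_grid:
                    inner = StratifiedKFold(n_splits=inner_k, shuffle=True,
                                            random_state=rep_seed)
                    search = GridSearchCV(est, dict(param_grid), cv=inner,
                                          scoring="roc_auc", n_jobs=1)
                    search.fit(X[train], y[train])
                    est = search.best_estimator_
                    fold_params.append(dict(search.best_params_))
                else:
                    est.fit(X[train], y[train])
                    fold_params.append({})
                fold_aurocs.append(roc_auc_score(y[test], _scores(est, X[test])))
            except Exception as exc:  # non-converging learner on this fold
                import warnings

                warnings.warn(f"{model_name}: fold {f} of repeat {rep} "
                              f"skipped ({exc})", RuntimeWarning)
                if rep not in flagged:
                    flagged.append(rep)
        if not fold_aurocs:
            raise RuntimeError(f"{model_name}: every fold failed in repeat {rep}")
        repeat_means.append(float(np.mean(fold_aurocs)))
        chosen.append(fold_params)
    arr = np.array(repeat_means)
    mean = float(arr.mean())
    half = 1.96 * arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return CVResult(
        model_name=model_name,
        repeat_aurocs=arr,
        mean_auroc=mean,
        ci95=(mean - half, mean + half),
        seeds=seeds,
        k=k,
        chosen_params=chosen,
        flagged_repeats=flagged,
    )


def compare_models(results: Sequence[CVResult]) -> pd.DataFrame:
    """Mean (95% CI) AUROC per model, best first.  Requires at least two
    results computed on identical fold assignments (same seeds and k); no
    significance test is applied."""
    if len(results) < 2:
        raise ValueError("need at least two CV results to compare")
    ref = results[0]
    for r in results[1:]:
        if r.seeds != ref.seeds or r.k != ref.k:
            raise ValueError("results were not computed on identical folds")
    rows = [
        {
            "model": r.model_name,
            "mean_auroc": r.mean_auroc,
            "ci_low": r.ci95[0],
            "ci_high": r.ci95[1],
            "repeats": len(r.repeat_aurocs),
        }
        for r in results
    ]
    return (pd.DataFrame(rows)
            .sort_values("mean_auroc", ascending=False)
            .reset_index(drop=True))
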