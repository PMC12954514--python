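"""Normal/abnormal lung-function classification from global perfusion scores.

Cases are labelled *abnormal* when DLCO < 60%, FEV1 < 70% or FEV1/FVC < 70
(conservative clinical thresholds; a case is normal only when all three
exceed their threshold).  Top-ranked global scores are then evaluated as
covariates of a logistic regression under leave-one-out cross-validation
(LOOCV): per fold, covariates are z-scored on the training cases, an
unpenalized maximum-likelihood fit is made (with a tiny 1e-8 ridge fallback
if the optimizer fails, e.g. on separable folds), and the held-out
probability is recorded.  Performance is summarized by ROC AUC over the
pooled held-out probabilities, plus F1/accuracy/confusion at threshold 0.5.

Collinearity among candidate covariates is diagnosed with variance inflation
factors (VIF = 1/(1-R^2) of a covariate regressed on the others, intercept
included) and with a *cross-group* VIF that regresses only on covariates
targeting *different* PFT measures, since covariates ranked for the same
measure are expected to be collinear by construction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score, roc_curve

from .containers import PftRecord

ABNORMAL_THRESHOLDS = {"DLCO": 60.0, "FEV1": 70.0, "FEV1_FVC": 70.0}
RIDGE_FALLBACK_ALPHA = 1e-8


@dataclass
class FunctionLabel:
    case_id: str
    label: str  # "normal" | "abnormal"
    triggered_by: tuple[str, ...]

    @property
    def is_abnormal(self) -> bool:
        return self.label == "abnormal"


def label_function(pft: PftRecord) -> FunctionLabel:
    """Label one case from its PFT thresholds (strict ``<`` comparisons).

    Requires DLCO to be present; callers decide how to handle missing-DLCO
    cases (the default protocol drops them from classification).
    """
    if pft.dlco_pct is None:
        raise ValueError(f"case {pft.case_id}: DLCO missing; exclude before labelling")
    triggers = []
    if pft.dlco_pct < ABNORMAL_THRESHOLDS["DLCO"]:
        triggers.append("DLCO")
    if pft.fev1_pct < ABNORMAL_THRESHOLDS["FEV1"]:
        triggers.append("FEV1")
    if pft.fev1_fvc < ABNORMAL_THRESHOLDS["FEV1_FVC"]:
        triggers.append("FEV1_FVC")
    label = "abnormal" if triggers else "normal"
    return FunctionLabel(pft.case_id, label, tuple(triggers))


def make_labels(records: list[PftRecord]) -> pd.Series:
    """0/1 label series (1 = abnormal) over the DLCO-complete subset."""
    usable = [r for r in records if r.dlco_pct is not None]
    return pd.Series(
        [int(label_function(r).is_abnormal) for r in usable],
        index=pd.Index([r.case_id for r in usable], name="case_id"),
        name="abnormal",
    )


@dataclass
class ModelReport:
    """LOOCV logistic-regression result for one covariate set."""

    covariate_ids: list[str]
    coef_mean: np.ndarray
    coef_sd: np.ndarray
    bias_mean: float
    bias_sd: float
    auc: float
    f1: float
    accuracy: float
    confusion: dict[str, int]  # TP / FP / TN / FN
    n_cases: int
    used_ridge_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {
                    "id": cid,
                    "coef_mean": float(m),
                    "coef_sd": float(s),
                }
                for cid, m, s in zip(self.covariate_ids, self.coef_mean, self.coef_sd)
            ],
            "bias_mean": self.bias_mean,
            "bias_sd": self.bias_sd,
            "auc": self.auc,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "confusion": self.confusion,
            "n_cases": self.n_cases,
            "used_ridge_fallback": self.used_ridge_fallback,
        }


class LoocvLogisticModel(BaseEstimator, ClassifierMixin):
    """Leave-one-out-validated logistic regression over standardized covariates.

    ``fit(X, y)`` runs the full LOOCV protocol and exposes the pooled held-out
    probabilities (``heldout_proba_``), fold-wise coefficients
    (``coef_mean_``/``coef_sd_`` on the standardized scale) and the summary
    metrics ``auc_``, ``f1_``, ``accuracy_``, ``confusion_``.  A final
    full-data refit backs ``predict``/``predict_proba``.
    """

    def __init__(self, threshold: float = 0.5, max_iter: int = 2000):
        self.threshold = threshold
        self.max_iter = max_iter

    def _fit_fold(self, X: np.ndarray, y: np.ndarray) -> LogisticRegression:
        # C=inf is sklearn's spelling of an unpenalized maximum-likelihood fit
        clf = LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=self.max_iter, tol=1e-10
        )
        try:
            with warnings.catch_warnings():
                # at tol=1e-10 lbfgs may stop at line-search precision limits;
                # finite coefficients are all the protocol needs
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
            if np.isfinite(clf.coef_).all() and np.isfinite(clf.intercept_).all():
                return clf
        except Exception:
            pass
        self._fallback_used = True
        clf = LogisticRegression(
            C=1.0 / RIDGE_FALLBACK_ALPHA, solver="lbfgs", max_iter=self.max_iter, tol=1e-10
        )
        clf.fit(X, y)
        return clf

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_cases, n_covariates) matching y")
        n = X.shape[0]
        if n < 6:
            raise ValueError(f"LOOCV needs n >= 6 cases, got {n}")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("both classes must be present")
        if np.isnan(X).any():
            raise ValueError("undefined covariate values in X")
        self._fallback_used = False

        proba = np.empty(n, dtype=np.float64)
        coefs = np.empty((n, X.shape[1]), dtype=np.float64)
        biases = np.empty(n, dtype=np.float64)
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            y_tr = y[train]
            if np.unique(y_tr).size < 2:
                raise RuntimeError(
                    f"degenerate LOOCV fold {i}: training split has one class"
                )
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            clf = self._fit_fold((X[train] - mu) / sd, y_tr)
            proba[i] = clf.predict_proba(((X[i] - mu) / sd).reshape(1, -1))[0, 1]
            coefs[i] = clf.coef_[0]
            biases[i] = clf.intercept_[0]

        self.heldout_proba_ = proba
        self.coef_mean_ = coefs.mean(axis=0)
        self.coef_sd_ = coefs.std(axis=0)
        self.bias_mean_ = float(biases.mean())
        self.bias_sd_ = float(biases.std())
        self.auc_ = float(roc_auc_score(y, proba))
        y_pred = (proba >= self.threshold).astype(int)
        self.f1_ = float(f1_score(y, y_pred, zero_division=0))
        self.accuracy_ = float((y_pred == y).mean())
        tn, fp, fn, tp = confusion_matrix(y, y_pred, labels=[0, 1]).ravel()
        self.confusion_ = {"TP": int(tp), "FP": int(fp), "TN": int(tn), "FN": int(fn)}
        self.n_cases_ = n
        self.used_ridge_fallback_ = self._fallback_used

        mu = X.mean(axis=0)
        sd = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
        self._final_mu, self._final_sd = mu, sd
        self._final_clf = self._fit_fold((X - mu) / sd, y)
        self.classes_ = classes
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self._final_clf.predict_proba((X - self._final_mu) / self._final_sd)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def report(self, covariate_ids: list[str] | None = None) -> ModelReport:
        ids = covariate_ids or [f"x{j}" for j in range(self.coef_mean_.size)]
        return ModelReport(
            covariate_ids=list(ids),
            coef_mean=self.coef_mean_,
            coef_sd=self.coef_sd_,
            bias_mean=self.bias_mean_,
            bias_sd=self.bias_sd_,
            auc=self.auc_,
            f1=self.f1_,
            accuracy=self.accuracy_,
            confusion=self.confusion_,
            n_cases=self.n_cases_,
            used_ridge_fallback=self.used_ridge_fallback_,
        )


def fit_logreg_loocv(X, y, threshold: float = 0.5, covariate_ids=None) -> ModelReport:
    """Functional wrapper over :class:`LoocvLogisticModel`."""
    model = LoocvLogisticModel(threshold=threshold).fit(X, y)
    return model.report(covariate_ids)


def roc_points(proba, y) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (fpr, tpr) and trapezoid AUC of pooled held-out probabilities."""
    y = np.asarray(y).ravel()
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, proba)
    return fpr, tpr, float(roc_auc_score(y, proba))


# ---------------------------------------------------------------------------
# collinearity diagnostics


def _r_squared(target: np.ndarray, regressors: np.ndarray) -> float:
    """R^2 of an OLS fit with intercept (empty regressor set -> 0)."""
    n = target.size
    design = np.column_stack([np.ones(n), regressors]) if regressors.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ beta
    ss_res = float(resid @ resid)
    centered = target - target.mean()
    ss_tot = float(centered @ centered)
    if ss_tot == 0.0:
        return 1.0  # constant covariate: perfectly 'explained' by the intercept
    return 1.0 - ss_res / ss_tot


def _vif_from_r2(r2: float, tol: float = 1e-12) -> float:
    if 1.0 - r2 < tol:
        return math.inf
    return 1.0 / (1.0 - r2)


def vif(X: pd.DataFrame | np.ndarray) -> pd.Series:
    """Full-multicollinearity VIF per covariate (exact collinearity -> inf)."""
    df = pd.DataFrame(X)
    a = df.to_numpy(dtype=np.float64)
    n, p = a.shape
    if n <= p + 1:
        raise ValueError(f"VIF needs n > p + 1 (n={n}, p={p})")
    out = {}
    for j, col in enumerate(df.columns):
        others = np.delete(a, j, axis=1)
        out[col] = _vif_from_r2(_r_squared(a[:, j], others))
    return pd.Series(out, name="vif")


def cross_group_vif(X: pd.DataFrame | np.ndarray, groups: dict) -> pd.Series:
    """VIF regressing each covariate only on covariates of *other* groups.

    ``groups`` maps covariate id -> PFT measure; within-measure collinearity
    (expected, since those covariates were ranked against the same measure)
    is thereby excluded from the diagnostic.
    """
    df = pd.DataFrame(X)
    a = df.to_numpy(dtype=np.float64)
    out = {}
    for j, col in enumerate(df.columns):
        other_idx = [
            i for i, c in enumerate(df.columns) if groups.get(c) != groups.get(col)
        ]
        regressors = a[:, other_idx] if other_idx else np.empty((a.shape[0], 0))
        if a.shape[0] <= len(other_idx) + 1:
            raise ValueError("cross-group VIF needs n > n_regressors + 1")
        out[col] = _vif_from_r2(_r_squared(a[:, j], regressors))
    return pd.Series(out, name="cross_group_vif")


# ---------------------------------------------------------------------------
# best-subset covariate search


@dataclass
class SubsetSearchResult:
    covariate_ids: tuple[str, ...]
    report: ModelReport
    n_subsets_evaluated: int = 0


def best_subset_search(
    candidates: pd.DataFrame,
    y,
    max_subset_size: int | None = None,
    threshold: float = 0.5,
) -> SubsetSearchResult:
    """Exhaustive LOOCV evaluation of covariate subsets.

    Every non-empty subset of the candidate columns (optionally capped at
    ``max_subset_size`` covariates) is scored by LOOCV AUC; ties break by
    higher F1, then fewer covariates, then canonical (sorted-key) ordering.
    """
    if candidates.shape[1] == 0:
        raise ValueError("empty candidate pool")
    if candidates.shape[1] > 15 and max_subset_size is None:
        raise ValueError(
            "pool > 15 covariates: the unrestricted search exceeds 2^15 - 1 subsets; "
            "set max_subset_size"
        )
    cols = sorted(candidates.columns)
    y = np.asarray(y, dtype=np.int64).ravel()
    cap = len(cols) if max_subset_size is None else min(max_subset_size, len(cols))
    best: tuple | None = None
    best_result: SubsetSearchResult | None = None
    n_eval = 0
    for size in range(1, cap + 1):
        for subset in itertools.combinations(cols, size):
            model = LoocvLogisticModel(threshold=threshold).fit(
                candidates.loc[:, list(subset)].to_numpy(), y
            )
            n_eval += 1
            # larger auc, larger f1, fewer covariates, earlier canonical order
            rank_key = (-model.auc_, -model.f1_, size, subset)
            if best is None or rank_key < best:
                best = rank_key
                best_result = SubsetSearchResult(
                    subset, model.report(list(subset)), n_eval
                )
    assert best_result is not None
    best_result.n_subsets_evaluated = n_eval
    return best_result


class BestSubsetSelector(BaseEstimator):
    """Estimator form of the exhaustive subset search.

    After ``fit(candidates, y)``: ``best_subset_``, ``report_`` and
    ``n_subsets_evaluated_``.
    """

    def __init__(self, max_subset_size: int | None = None, threshold: float = 0.5):
        self.max_subset_size = max_subset_size
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y):
        res = best_subset_search(X, y, self.max_subset_size, self.threshold)
        self.best_subset_ = res.covariate_ids
        self.report_ = res.report
        self.n_subsets_evaluated_ = res.n_subsets_evaluated
        return self


__all__ = [
    "ABNORMAL_THRESHOLDS",
    "FunctionLabel",
    "label_function",
    "make_labels",
    "ModelReport",
    "LoocvLogisticModel",
    "fit_logreg_loocv",
    "roc_points",
    "vif",
    "cross_group_vif",
    "SubsetSearchResult",
    "best_subset_search",
    "BestSubsetSelector",
]
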