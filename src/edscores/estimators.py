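"""Scikit-learn style estimators wrapping the scoring and evaluation core.

Three composable pieces:

* :class:`SeverityScorer` — a stateless transformer turning a flat
  patient DataFrame into columns of RAPS/REMS/MEWS/MEDS totals; drops
  into sklearn pipelines ahead of any classifier.
* :class:`ScoreLogisticModel` — the univariate logistic probability-of-
  death model p = 1/(1+exp(-(b0 + b1*score))), fitted by the package's
  own IRLS; a sklearn-compatible binary classifier.
* :class:`YoudenCutoffClassifier` — dichotomizes a score at the cutoff
  maximizing Youden's J on the training data, the rule used to derive
  published sensitivity/specificity rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import stats
from .scoring import (
    Avpu,
    MedsCriteria,
    Vitals,
    meds_score,
    mews_score,
    raps_score,
    rems_score,
)

__all__ = ["SeverityScorer", "ScoreLogisticModel", "YoudenCutoffClassifier", "SYSTEMS"]

SYSTEMS = ("RAPS", "REMS", "MEWS", "MEDS")

_VITALS_FIELDS = (
    "pulse_rate",
    "respiratory_rate",
    "systolic_bp",
    "mean_arterial_pressure",
    "temperature",
    "spo2",
    "gcs",
    "avpu",
)
_MEDS_FIELDS = (
    "age",
    "terminal_illness",
    "septic_shock",
    "platelet_count",
    "band_percent",
    "lower_respiratory_infection",
    "nursing_home_resident",
    "altered_mental_status",
    "oxygen_by_mask",
)


def _row_vitals(row: pd.Series) -> Vitals:
    kw = {}
    for f in _VITALS_FIELDS:
        v = row.get(f)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            kw[f] = None
        elif f == "avpu":
            kw[f] = Avpu(v)
        elif f == "gcs":
            kw[f] = int(v)
        else:
            kw[f] = float(v)
    return Vitals(**kw)


def _row_meds(row: pd.Series) -> MedsCriteria:
    kw = {}
    for f in _MEDS_FIELDS:
        v = row.get(f)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            kw[f] = None
        elif f in ("age", "platelet_count", "band_percent"):
            kw[f] = float(v)
        else:
            kw[f] = bool(v)
    for flag in ("terminal_illness", "septic_shock", "lower_respiratory_infection",
                 "nursing_home_resident", "oxygen_by_mask"):
        if kw.get(flag) is None:
            kw[flag] = False
    return MedsCriteria(**kw)


def score_row(row: pd.Series, system: str, impute_normal: bool = False) -> int:
    """Score one flat patient row under one system; returns the total."""
    vitals = _row_vitals(row)
    system = system.upper()
    if system == "RAPS":
        return raps_score(vitals, impute_normal=impute_normal).total
    if system == "REMS":
        return rems_score(vitals, float(row["age"]), impute_normal=impute_normal).total
    if system == "MEWS":
        return mews_score(vitals, impute_normal=impute_normal).total
    if system == "MEDS":
        return meds_score(vitals, _row_meds(row)).total
    raise ValueError(f"unknown scoring system {system!r}")


def score_dataframe(df: pd.DataFrame, systems=SYSTEMS, impute_normal: bool = False) -> pd.DataFrame:
    """Append lowercase score columns (raps, rems, mews, meds) to a copy of ``df``."""
    out = df.copy()
    for system in systems:
        out[system.lower()] = [
            score_row(row, system, impute_normal) for _, row in df.iterrows()
        ]
    return out


class SeverityScorer(TransformerMixin, BaseEstimator):
    """Transformer computing ED severity score totals from patient columns.

    Parameters
    ----------
    systems : tuple of str, default all four
        Scoring systems to compute, among RAPS / REMS / MEWS / MEDS.
    impute_normal : bool, default False
        Substitute zero-band midpoints for missing vitals (logged)
        instead of raising.

    The transformer is stateless; ``fit`` only records the input
    column names.  ``transform`` expects a DataFrame with the cohort
    CSV columns and returns an (n_samples, n_systems) integer array.
    """

    def __init__(self, systems=SYSTEMS, impute_normal: bool = False):
        self.systems = systems
        self.impute_normal = impute_normal

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("SeverityScorer expects a patient DataFrame")
        unknown = [s for s in self.systems if s.upper() not in SYSTEMS]
        if unknown or not self.systems:
            raise ValueError(f"systems must be a non-empty subset of {SYSTEMS}, got {self.systems!r}")
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self)
        scored = score_dataframe(X, self.systems, self.impute_normal)
        return scored[[s.lower() for s in self.systems]].to_numpy(dtype=int)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([s.lower() for s in self.systems], dtype=object)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.requires_fit = False
        return tags


class ScoreLogisticModel(ClassifierMixin, BaseEstimator):
    """Univariate logistic probability-of-death model over a severity score.

    Fitted by the package's iteratively reweighted least squares
    (:func:`edscores.stats.fit_univariate_logistic`); prediction uses
    the logit formula p = 1/(1+exp(-(b0 + b1*x))).

    Attributes
    ----------
    intercept_ : float            fitted b0
    coef_ : ndarray (1, 1)        fitted b1
    converged_ : bool             gradient max-norm below ``tol``
    n_iter_ : int                 IRLS iterations used
    log_likelihood_ : float       maximized log-likelihood
    classes_ : ndarray            [0, 1]
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("ScoreLogisticModel is univariate: X must have one column")
            x = x[:, 0]
        fit = stats.fit_univariate_logistic(x, np.asarray(y), tol=self.tol, max_iter=self.max_iter)
        self.fit_ = fit
        self.intercept_ = fit.beta0
        self.coef_ = np.array([[fit.beta1]])
        self.converged_ = fit.converged
        self.n_iter_ = fit.iterations
        self.log_likelihood_ = fit.log_likelihood
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def _scores(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        return x[:, 0] if x.ndim == 2 else x

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        p = stats.predict_probability(self.fit_, self._scores(X))
        p = np.atleast_1d(p)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        return self.intercept_ + self.coef_[0, 0] * self._scores(X)


class YoudenCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Dichotomize a severity score at the Youden-optimal ROC cutoff.

    ``fit`` builds the ROC curve of score against outcome and stores the
    threshold maximizing J = sensitivity + specificity - 1 (ties toward
    higher specificity); ``predict`` labels a patient positive
    (predicted death) iff score >= ``cutoff_``.

    Attributes
    ----------
    cutoff_ : float     Youden-optimal threshold
    auc_ : float        area under the training ROC curve
    roc_ : RocCurve     the full training curve
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        y = np.asarray(y)
        self.roc_ = stats.roc_curve(x, y)
        self.auc_ = self.roc_.auc
        self.cutoff_ = stats.optimal_cutoff(self.roc_)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return (x >= self.cutoff_).astype(int)

    def metrics(self, X, y) -> stats.ClassifierMetrics:
        """Confusion-matrix characteristics of the fitted cutoff on (X, y)."""
        check_is_fitted(self, "cutoff_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return stats.confusion_metrics(x, np.asarray(y), self.cutoff_)
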