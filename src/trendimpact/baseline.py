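"""Baseline trend models: OLS extrapolation of a prevalence series.

The no-events ("baseline") forecast is an ordinary least-squares fit of
prevalence on calendar year, extrapolated over the horizon. Three functional
forms are supported — linear, quadratic, and log-linear (log prevalence on
year) — compared by adjusted R². Calendar years are used directly as the
regressor: the historical points are unevenly spaced (2008, 2010, 2013,
2016-2018) and the fit quality depends on that spacing.

Fits are unweighted: survey sample sizes are metadata, not regression
weights. Baseline parameter uncertainty is deliberately not propagated into
the scenario bands — those come from the event-impact percentiles alone.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .timeseries import PrevalenceSeries

__all__ = [
    "BaselineTrend",
    "BaselineModel",
    "MODEL_FORMS",
    "fit_baseline",
    "compare_models",
    "predict_baseline",
]

logger = logging.getLogger(__name__)

MODEL_FORMS = ("linear", "quadratic", "log-linear")

# number of slope terms k per form (intercept excluded)
_N_SLOPES = {"linear": 1, "quadratic": 2, "log-linear": 1}


class BaselineTrend(RegressorMixin, BaseEstimator):
    """Trend regression of prevalence (%) on calendar year.

    scikit-learn style estimator: ``fit(X, y)`` with ``X`` a column of
    calendar years and ``y`` prevalence percentages; ``predict(X)`` evaluates
    the fitted trend, clipped to [0, 100].

    Parameters
    ----------
    model_form : {"linear", "quadratic", "log-linear"}, default "linear"
        Functional form. "log-linear" regresses log prevalence on year and
        back-transforms predictions; its R² is computed on the prevalence
        scale so forms are comparable.

    Attributes
    ----------
    intercept_ : float
        Intercept on the raw calendar-year scale (fitted-response scale for
        log-linear).
    coef_ : ndarray of shape (k,)
        Slope terms: ``[slope]`` (%/year) for linear/log-linear,
        ``[slope, curvature]`` for quadratic.
    r_squared_, adj_r_squared_ : float
        Coefficient of determination on the prevalence scale and its
        small-sample adjustment ``1 - (1-R²)(n-1)/(n-k-1)``.
    n_obs_ : int
    fit_years_ : ndarray
        Years used in the fit.
    """

    def __init__(self, model_form: str = "linear"):
        self.model_form = model_form

    # -- internal design helpers ------------------------------------------
    def _design(self, years: np.ndarray) -> np.ndarray:
        if self.model_form in ("linear", "log-linear"):
            X = years[:, None]
        elif self.model_form == "quadratic":
            X = np.column_stack([years, (years - self._year_center_) ** 2])
        else:
            raise ValueError(
                f"unknown model_form {self.model_form!r}; choose from {MODEL_FORMS}"
            )
        return sm.add_constant(X, has_constant="add")

    def fit(self, X, y):
        if self.model_form not in MODEL_FORMS:
            raise ValueError(
                f"unknown model_form {self.model_form!r}; choose from {MODEL_FORMS}"
            )
        years = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if years.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        k = _N_SLOPES[self.model_form]
        if len(years) < k + 2:
            raise ValueError(
                f"{self.model_form} fit needs at least {k + 2} observations, "
                f"got {len(years)}"
            )
        if np.ptp(years) == 0:
            raise ValueError("singular design: all years identical")
        # centre the quadratic term only, for conditioning; slope term stays
        # on the raw calendar-year scale
        self._year_center_ = years.mean()
        response = y
        if self.model_form == "log-linear":
            if np.any(y <= 0):
                raise ValueError("log-linear form requires strictly positive prevalence")
            response = np.log(y)
        ols = sm.OLS(response, self._design(years)).fit()
        self._ols_result_ = ols
        self.intercept_ = float(ols.params[0])
        self.coef_ = np.asarray(ols.params[1:], dtype=float)
        self.n_obs_ = int(len(years))
        self.fit_years_ = years.copy()
        # diagnostics on the prevalence scale (differs from the OLS R² only
        # for the log-linear form)
        fitted = self._evaluate(years)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot
        self.adj_r_squared_ = 1.0 - (1.0 - self.r_squared_) * (self.n_obs_ - 1) / (
            self.n_obs_ - k - 1
        )
        self.n_params_ = k + 1
        return self

    def _evaluate(self, years: np.ndarray) -> np.ndarray:
        """Un-clipped trend values at the given years."""
        pred = self._design(np.asarray(years, dtype=float)) @ np.concatenate(
            [[self.intercept_], self.coef_]
        )
        if self.model_form == "log-linear":
            pred = np.exp(pred)
        return pred

    def predict(self, X) -> np.ndarray:
        """Evaluate the trend at calendar years ``X``, clipped to [0, 100]."""
        check_is_fitted(self, "coef_")
        years = np.asarray(X, dtype=float).reshape(-1)
        pred = self._evaluate(years)
        clipped = np.clip(pred, 0.0, 100.0)
        if np.any(clipped != pred):
            logger.warning(
                "baseline prediction clipped to [0, 100] for %d of %d years",
                int(np.sum(clipped != pred)), len(pred),
            )
        return clipped

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "model_form": self.model_form,
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "year_center": float(self._year_center_),
            "r_squared": self.r_squared_,
            "adj_r_squared": self.adj_r_squared_,
            "n_obs": self.n_obs_,
            "fit_years": self.fit_years_.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineTrend":
        model = cls(model_form=d["model_form"])
        model.intercept_ = float(d["intercept"])
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model._year_center_ = float(d["year_center"])
        model.r_squared_ = float(d["r_squared"])
        model.adj_r_squared_ = float(d["adj_r_squared"])
        model.n_obs_ = int(d["n_obs"])
        model.fit_years_ = np.asarray(d["fit_years"], dtype=float)
        model.n_params_ = len(model.coef_) + 1
        return model

    @classmethod
    def from_json(cls, path) -> "BaselineTrend":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Backwards-friendly alias matching the domain vocabulary.
BaselineModel = BaselineTrend


def fit_baseline(series: PrevalenceSeries, model_form: str = "linear") -> BaselineTrend:
    """Fit a baseline trend of the chosen form to a prevalence series."""
    if len(series) < 3:
        raise ValueError(f"need at least 3 observations to fit, got {len(series)}")
    return BaselineTrend(model_form=model_form).fit(series.years, series.prevalences)


def compare_models(
    series: PrevalenceSeries, candidates=MODEL_FORMS
) -> pd.DataFrame:
    """Fit each candidate form and rank by adjusted R² (ties: fewer parameters).

    Returns a diagnostics table with one row per candidate, best first.
    """
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    rows = []
    for form in candidates:
        model = fit_baseline(series, model_form=form)
        rows.append(
            {
                "model_form": form,
                "r_squared": model.r_squared_,
                "adj_r_squared": model.adj_r_squared_,
                "n_params": model.n_params_,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["adj_r_squared", "n_params"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def predict_baseline(model: BaselineTrend, years) -> np.ndarray:
    """Evaluate a fitted baseline at the given calendar years (clipped to [0,100])."""
    return model.predict(np.asarray(years, dtype=float))
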