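"""Trend-impact Monte-Carlo engine.

The engine deflects a fitted baseline trend by simulating expert-elicited
future events. For one event and one repetition, the forecast horizon is
walked year by year: a uniform draw r ~ U(0, 1) is compared with the event's
elicited occurrence probability for that year; when the rule fires the event
"occurs", its impact (signed prevalence percentage points) is added to that
year and every later year, and — in the default single-occurrence mode — no
further draws are made for that event in that repetition. Trajectories are
summed over events within a repetition, accumulated into an
n_reps x n_years impact matrix, and column-wise 2.5th/50th/97.5th
percentiles are added to the baseline prediction to form the scenario
forecast with its simulated 95% band.

Occurrence rules
----------------
``standard`` fires when r < p, so events with larger elicited probabilities
occur more often — the behaviour the scenario curves require. ``literal``
fires when r > p (the inverted comparison, kept selectable for fidelity to
one published wording of the algorithm).

Scenario comparability uses common random numbers: each event owns a random
substream derived from (seed, event_id), so the negative-only, positive-only
and combined scenarios reuse identical draws per event. Adding an
all-negative event therefore can never raise any repetition's total impact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .baseline import BaselineTrend, fit_baseline
from .delphi import Driver

__all__ = [
    "SimulationConfig",
    "ImpactMatrix",
    "TIAResult",
    "TrendImpactForecaster",
    "simulate_event_rep",
    "simulate_event_matrix",
    "compute_impact_matrix",
    "run_tia",
    "run_scenarios",
    "percentiles_by_year",
    "DEFAULT_HORIZON",
]

DEFAULT_HORIZON = tuple(range(2021, 2032))
PERCENTILE_LEVELS = (2.5, 50.0, 97.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo run parameters.

    Parameters
    ----------
    n_reps : int
        Number of repetitions (default 10,000).
    seed : int
        Root seed; every event's substream is derived from it.
    horizon : sequence of int
        Forecast years, strictly increasing (default 2021-2031 inclusive).
    occurrence_rule : {"standard", "literal"}
        "standard" fires when r < p; "literal" when r > p.
    single_occurrence : bool
        If True (default) an event occurs at most once per repetition and
        its onset-year impact persists to the horizon end. If False every
        firing year adds its own impact, each persisting onward.
    impact_profile : {"onset", "per_year"}
        With single occurrence: "onset" (default) persists the onset-year
        impact; "per_year" accumulates each post-onset year's own impact.
        Ignored when single_occurrence is False.
    """

    n_reps: int = 10_000
    seed: int = 0
    horizon: tuple[int, ...] = DEFAULT_HORIZON
    occurrence_rule: str = "standard"
    single_occurrence: bool = True
    impact_profile: str = "onset"

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizon", tuple(int(y) for y in self.horizon))
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.horizon:
            raise ValueError("horizon must be non-empty")
        if any(b <= a for a, b in zip(self.horizon, self.horizon[1:])):
            raise ValueError("horizon years must be strictly increasing")
        if self.occurrence_rule not in ("standard", "literal"):
            raise ValueError(f"unknown occurrence_rule {self.occurrence_rule!r}")
        if self.impact_profile not in ("onset", "per_year"):
            raise ValueError(f"unknown impact_profile {self.impact_profile!r}")


@dataclass(frozen=True)
class ImpactMatrix:
    """Total event impact per repetition and horizon year (percentage points)."""

    values: np.ndarray  # shape (n_reps, n_years)
    horizon: tuple[int, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(self.horizon):
            raise ValueError(
                f"impact matrix shape {values.shape} does not match "
                f"{len(self.horizon)}-year horizon"
            )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class TIAResult:
    """Scenario forecast: baseline, impact percentiles, and adjusted band."""

    horizon: tuple[int, ...]
    baseline: np.ndarray
    impact_median: np.ndarray
    impact_lo: np.ndarray
    impact_hi: np.ndarray
    forecast: np.ndarray
    forecast_lo: np.ndarray
    forecast_hi: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.horizon)
        for name in ("baseline", "impact_median", "impact_lo", "impact_hi",
                     "forecast", "forecast_lo", "forecast_hi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            object.__setattr__(self, name, arr)
        if np.any(self.impact_lo > self.impact_median + 1e-12) or np.any(
            self.impact_median > self.impact_hi + 1e-12
        ):
            raise ValueError("impact percentiles must satisfy lo <= median <= hi")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "year": np.asarray(self.horizon, dtype=int),
                "baseline": self.baseline,
                "impact_median": self.impact_median,
                "impact_lo": self.impact_lo,
                "impact_hi": self.impact_hi,
                "forecast": self.forecast,
                "forecast_lo": self.forecast_lo,
                "forecast_hi": self.forecast_hi,
            }
        )


def _event_rng(seed: int, event_id: str) -> np.random.Generator:
    """Dedicated substream per event: identical draws across scenario subsets."""
    digest = hashlib.sha256(event_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _fires(u: np.ndarray, p: np.ndarray, rule: str) -> np.ndarray:
    return u < p if rule == "standard" else u > p


def simulate_event_rep(
    driver: Driver, config: SimulationConfig, u: Sequence[float]
) -> np.ndarray:
    """One repetition of one event: walk the horizon, return its impact trajectory.

    ``u`` supplies the uniform draws, one per horizon year (later entries are
    unused once a single-occurrence event has fired). Written as the literal
    year-by-year walk; the vectorised :func:`simulate_event_matrix` is tested
    to agree with it draw for draw.
    """
    horizon = config.horizon
    p = driver.probability_array(horizon)
    impact = driver.impact_array(horizon)
    u = np.asarray(u, dtype=float)
    if u.shape[0] < len(horizon):
        raise ValueError("need one uniform draw per horizon year")
    traj = np.zeros(len(horizon))
    cumulative = 0.0
    fired_once = False
    for t in range(len(horizon)):
        if fired_once and config.single_occurrence:
            if config.impact_profile == "per_year":
                cumulative += impact[t]
            traj[t] = cumulative
            continue
        if _fires(u[t], p[t], config.occurrence_rule):
            cumulative += impact[t]
            fired_once = True
        traj[t] = cumulative
    return traj


def simulate_event_matrix(
    driver: Driver, config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """All repetitions of one event, vectorised: shape (n_reps, n_years)."""
    horizon = config.horizon
    p = driver.probability_array(horizon)
    impact = driver.impact_array(horizon)
    if rng is None:
        rng = _event_rng(config.seed, driver.event_id)
    n, T = config.n_reps, len(horizon)
    u = rng.uniform(size=(n, T))
    fired = _fires(u, p[None, :], config.occurrence_rule)
    if not config.single_occurrence:
        # every firing year adds its own impact, persisting onward
        return np.cumsum(np.where(fired, impact[None, :], 0.0), axis=1)
    any_fired = fired.any(axis=1)
    onset = np.argmax(fired, axis=1)  # first firing year (0 when none fired)
    cols = np.arange(T)
    active = any_fired[:, None] & (cols[None, :] >= onset[:, None])
    if config.impact_profile == "onset":
        traj = np.where(active, impact[onset][:, None], 0.0)
    else:
        # accumulate each post-onset year's own impact
        csum = np.cumsum(impact)
        offset = np.where(onset > 0, csum[onset - 1], 0.0)
        traj = np.where(active, csum[None, :] - offset[:, None], 0.0)
    return traj


def compute_impact_matrix(
    drivers: Sequence[Driver], config: SimulationConfig
) -> ImpactMatrix:
    """Sum per-event trajectories into the n_reps x n_years total-impact matrix."""
    total = np.zeros((config.n_reps, len(config.horizon)))
    for driver in drivers:
        total += simulate_event_matrix(driver, config)
    return ImpactMatrix(values=total, horizon=config.horizon)


def percentiles_by_year(matrix: ImpactMatrix, levels: Sequence[float]) -> np.ndarray:
    """Column-wise empirical percentiles (linear interpolation between order stats).

    Returns an array of shape (len(levels), n_years).
    """
    levels = np.asarray(levels, dtype=float)
    if np.any((levels < 0) | (levels > 100)):
        raise ValueError("percentile levels must lie in [0, 100]")
    if matrix.values.size == 0:
        raise ValueError("empty impact matrix")
    return np.percentile(matrix.values, levels, axis=0, method="linear")


def run_tia(
    baseline: BaselineTrend, drivers: Sequence[Driver], config: SimulationConfig
) -> TIAResult:
    """Full trend-impact run: simulate, take percentiles, adjust the baseline.

    With an empty driver collection the forecast equals the baseline with a
    zero-width band. Deterministic given the config seed.
    """
    drivers = list(drivers)
    base = baseline.predict(np.asarray(config.horizon, dtype=float))
    matrix = compute_impact_matrix(drivers, config)
    lo, med, hi = percentiles_by_year(matrix, PERCENTILE_LEVELS)
    return TIAResult(
        horizon=config.horizon,
        baseline=base,
        impact_median=med,
        impact_lo=lo,
        impact_hi=hi,
        forecast=np.clip(base + med, 0.0, 100.0),
        forecast_lo=np.clip(base + lo, 0.0, 100.0),
        forecast_hi=np.clip(base + hi, 0.0, 100.0),
    )


def run_scenarios(
    baseline: BaselineTrend, drivers: Sequence[Driver], config: SimulationConfig
) -> dict[str, TIAResult]:
    """Negative-only, positive-only, and combined scenario runs.

    Per-event substreams make the three runs use common random numbers, so
    scenario orderings are exact per repetition rather than statistical. An
    empty partition yields a baseline-equal result.
    """
    drivers = list(drivers)
    negative = [d for d in drivers if d.direction == "negative"]
    positive = [d for d in drivers if d.direction == "positive"]
    return {
        "negative": run_tia(baseline, negative, config),
        "positive": run_tia(baseline, positive, config),
        "combined": run_tia(baseline, drivers, config),
    }


class TrendImpactForecaster(BaseEstimator):
    """Baseline trend + event simulation as one scikit-learn style estimator.

    ``fit(X, y)`` takes historical calendar years and prevalence percentages,
    fits the baseline trend, and runs the Monte-Carlo simulation over the
    horizon. ``predict(X)`` returns the median scenario forecast at the
    requested years (baseline-only for years outside the horizon, e.g. the
    historical period).

    Parameters mirror :class:`SimulationConfig` plus the baseline
    ``model_form`` and the ``drivers`` to simulate.

    Attributes
    ----------
    baseline_ : BaselineTrend
        The fitted trend model.
    result_ : TIAResult
        Combined-scenario forecast over the horizon.
    scenarios_ : dict
        Negative-only / positive-only / combined TIAResult values.
    """

    def __init__(
        self,
        drivers: Sequence[Driver] = (),
        model_form: str = "linear",
        n_reps: int = 10_000,
        seed: int = 0,
        horizon: Sequence[int] = DEFAULT_HORIZON,
        occurrence_rule: str = "standard",
        single_occurrence: bool = True,
    ):
        self.drivers = drivers
        self.model_form = model_form
        self.n_reps = n_reps
        self.seed = seed
        self.horizon = horizon
        self.occurrence_rule = occurrence_rule
        self.single_occurrence = single_occurrence

    def _config(self) -> SimulationConfig:
        return SimulationConfig(
            n_reps=self.n_reps,
            seed=self.seed,
            horizon=tuple(self.horizon),
            occurrence_rule=self.occurrence_rule,
            single_occurrence=self.single_occurrence,
        )

    def fit(self, X, y):
        years = np.asarray(X, dtype=float).reshape(-1)
        self.baseline_ = BaselineTrend(model_form=self.model_form).fit(years, y)
        config = self._config()
        self.scenarios_ = run_scenarios(self.baseline_, list(self.drivers), config)
        self.result_ = self.scenarios_["combined"]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        years = np.asarray(X, dtype=float).reshape(-1)
        base = self.baseline_.predict(years)
        horizon_index = {y: i for i, y in enumerate(self.result_.horizon)}
        out = base.copy()
        for j, year in enumerate(years):
            i = horizon_index.get(int(year))
            if i is not None:
                out[j] = self.result_.forecast[i]
        return out
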