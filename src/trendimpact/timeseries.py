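"""Prevalence time-series containers and CSV I/O.

The historical input to a trend-impact forecast is a short annual series of
prevalence percentages (here: overweight/obesity among 7-18 year olds from
the CASPIAN school surveys and the national SIB health-information system).
Observations carry an optional survey sample size, which is kept as metadata
only — the baseline trend is fitted unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrevalenceObservation",
    "PrevalenceSeries",
    "load_prevalence",
    "builtin_table1",
    "write_forecast",
    "read_forecast",
    "PREVALENCE_CSV_COLUMNS",
    "FORECAST_CSV_COLUMNS",
]

PREVALENCE_CSV_COLUMNS = ["year", "prevalence_percent", "sample_size", "age_range"]
FORECAST_CSV_COLUMNS = ["year", "baseline", "impact_median", "lo_2.5", "hi_97.5", "forecast"]


@dataclass(frozen=True)
class PrevalenceObservation:
    """One annual prevalence measurement.

    Parameters
    ----------
    year : int
        Gregorian calendar year of the survey.
    prevalence : float
        Percent of the population affected, in [0, 100].
    sample_size : int, optional
        Number of subjects surveyed; metadata only.
    age_range : str, optional
        Free-text age range covered by the survey.
    """

    year: int
    prevalence: float
    sample_size: int | None = None
    age_range: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 100.0:
            raise ValueError(
                f"prevalence must be in [0, 100], got {self.prevalence!r} "
                f"for year {self.year}"
            )
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValueError(
                f"sample_size must be positive, got {self.sample_size!r} "
                f"for year {self.year}"
            )


@dataclass(frozen=True)
class PrevalenceSeries:
    """An ordered annual prevalence series with strictly increasing years."""

    observations: tuple[PrevalenceObservation, ...]

    def __init__(self, observations: Iterable[PrevalenceObservation]) -> None:
        obs = tuple(sorted(observations, key=lambda o: o.year))
        years = [o.year for o in obs]
        dupes = {y for y in years if years.count(y) > 1}
        if dupes:
            raise ValueError(f"duplicate years in series: {sorted(dupes)}")
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[PrevalenceObservation]:
        return iter(self.observations)

    @property
    def years(self) -> np.ndarray:
        return np.array([o.year for o in self.observations], dtype=float)

    @property
    def prevalences(self) -> np.ndarray:
        return np.array([o.prevalence for o in self.observations], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [o.year for o in self.observations],
                "prevalence_percent": [o.prevalence for o in self.observations],
                "sample_size": [o.sample_size for o in self.observations],
                "age_range": [o.age_range for o in self.observations],
            }
        )


def load_prevalence(path) -> PrevalenceSeries:
    """Read a prevalence CSV (``year,prevalence_percent,sample_size,age_range``).

    ``sample_size`` and ``age_range`` may be empty. Rows are validated and the
    series is returned sorted by year.

    Raises
    ------
    ValueError
        On a malformed row, an out-of-range prevalence, or a duplicate year;
        the message names the offending row.
    """
    df = pd.read_csv(path, dtype={"age_range": "string"})
    missing = [c for c in ("year", "prevalence_percent") if c not in df.columns]
    if missing:
        raise ValueError(f"prevalence CSV missing required columns: {missing}")
    observations = []
    for idx, row in df.iterrows():
        try:
            sample_size = row.get("sample_size")
            sample_size = None if pd.isna(sample_size) else int(sample_size)
            age_range = row.get("age_range")
            age_range = None if pd.isna(age_range) else str(age_range)
            observations.append(
                PrevalenceObservation(
                    year=int(row["year"]),
                    prevalence=float(row["prevalence_percent"]),
                    sample_size=sample_size,
                    age_range=age_range,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid prevalence row {idx} ({dict(row)}): {exc}") from exc
    return PrevalenceSeries(observations)


def write_prevalence(series: PrevalenceSeries, path) -> None:
    """Write a series in the prevalence CSV schema (round-trips with load)."""
    series.to_frame().to_csv(path, index=False)


# Overweight/obesity prevalence among Iranian children and adolescents,
# CASPIAN surveys (2008-2013) and SIB system (2016-2018). 2019 is absent
# (COVID-19 interrupted the school assessments) and is not imputed.
_TABLE1_ROWS = (
    (2008, 17.6, 5088, "10-18"),
    (2010, 21.2, 13487, "7-18"),
    (2013, 20.6, 14274, "7-18"),
    (2016, 21.7, 344682, "7-18"),
    (2017, 23.1, 280260, "7-18"),
    (2018, 23.4, 282165, "7-18"),
)


def builtin_table1() -> PrevalenceSeries:
    """The packaged six-point historical series (childhood overweight/obesity, Iran)."""
    return PrevalenceSeries(
        PrevalenceObservation(year=y, prevalence=p, sample_size=n, age_range=a)
        for y, p, n, a in _TABLE1_ROWS
    )


def write_forecast(result, path) -> None:
    """Write a scenario forecast as CSV, one row per horizon year.

    Columns: ``year,baseline,impact_median,lo_2.5,hi_97.5,forecast`` where
    ``lo_2.5``/``hi_97.5`` are the simulated 95% band of the forecast and
    ``forecast`` is baseline plus the median total impact.
    """
    df = pd.DataFrame(
        {
            "year": np.asarray(result.horizon, dtype=int),
            "baseline": result.baseline,
            "impact_median": result.impact_median,
            "lo_2.5": result.forecast_lo,
            "hi_97.5": result.forecast_hi,
            "forecast": result.forecast,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_forecast(path) -> pd.DataFrame:
    """Read a forecast CSV written by :func:`write_forecast`."""
    df = pd.read_csv(path)
    missing = [c for c in FORECAST_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forecast CSV missing columns: {missing}")
    return df
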