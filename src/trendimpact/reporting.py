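"""Scenario tables, plots, and run reports."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baseline import BaselineTrend
from .delphi import Driver
from .engine import SimulationConfig, TIAResult
from .timeseries import PrevalenceSeries

__all__ = [
    "scenario_table",
    "plot_scenarios",
    "make_scenario_figure",
    "RunReport",
    "build_report",
]


def scenario_table(results: Mapping[str, TIAResult], round_to: int | None = None) -> pd.DataFrame:
    """Flatten scenario results into a long per-year table.

    One row per (scenario, year) with columns ``scenario, year, baseline,
    forecast, lo, hi``. Full precision by default; pass ``round_to=2`` for
    display. All scenarios must share a horizon.
    """
    if not results:
        raise ValueError("no scenario results")
    horizons = {r.horizon for r in results.values()}
    if len(horizons) != 1:
        raise ValueError(f"scenario horizons differ: {sorted(horizons)}")
    rows = []
    for name, res in results.items():
        for i, year in enumerate(res.horizon):
            rows.append(
                {
                    "scenario": name,
                    "year": int(year),
                    "baseline": res.baseline[i],
                    "forecast": res.forecast[i],
                    "lo": res.forecast_lo[i],
                    "hi": res.forecast_hi[i],
                }
            )
    table = pd.DataFrame(rows)
    if round_to is not None:
        for col in ("baseline", "forecast", "lo", "hi"):
            table[col] = table[col].round(round_to)
    return table


def make_scenario_figure(
    results: Mapping[str, TIAResult],
    history: PrevalenceSeries | None = None,
):
    """Build the scenario figure: one line per scenario, shaded 95% bands,
    dashed baseline, historical observations as points. Returns the Figure."""
    if not results:
        raise ValueError("no scenario results")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    first = next(iter(results.values()))
    years = np.asarray(first.horizon)
    ax.plot(years, first.baseline, "k--", label="baseline")
    for name, res in results.items():
        ax.plot(np.asarray(res.horizon), res.forecast, label=name)
        ax.fill_between(np.asarray(res.horizon), res.forecast_lo, res.forecast_hi, alpha=0.2)
    if history is not None:
        ax.scatter(history.years, history.prevalences, color="black", zorder=5,
                   label="observed")
    ax.set_xlabel("year")
    ax.set_ylabel("prevalence (%)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_scenarios(
    results: Mapping[str, TIAResult],
    path,
    history: PrevalenceSeries | None = None,
) -> None:
    """Plot scenario forecasts and write the figure to ``path`` (.png/.svg)."""
    import matplotlib.pyplot as plt

    fig = make_scenario_figure(results, history=history)
    fig.savefig(path)
    plt.close(fig)


@dataclass(frozen=True)
class RunReport:
    """A complete run record: config echo, fit diagnostics, scenario tables, roster."""

    config: dict
    baseline_diagnostics: dict
    scenario_tables: pd.DataFrame
    driver_roster: pd.DataFrame

    def to_json(self, path=None) -> str:
        payload = {
            "config": self.config,
            "baseline_diagnostics": self.baseline_diagnostics,
            "scenarios": self.scenario_tables.to_dict(orient="records"),
            "drivers": self.driver_roster.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_report(
    baseline: BaselineTrend,
    drivers: Sequence[Driver],
    results: Mapping[str, TIAResult],
    config: SimulationConfig,
) -> RunReport:
    """Assemble a run report from a fitted baseline and scenario results."""
    roster = pd.DataFrame(
        {
            "event_id": [d.event_id for d in drivers],
            "name": [d.name for d in drivers],
            "direction": [d.direction for d in drivers],
        }
    )
    return RunReport(
        config={
            "n_reps": config.n_reps,
            "seed": config.seed,
            "horizon": list(config.horizon),
            "occurrence_rule": config.occurrence_rule,
            "single_occurrence": config.single_occurrence,
        },
        baseline_diagnostics=baseline.to_dict(),
        scenario_tables=scenario_table(results),
        driver_roster=roster,
    )
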