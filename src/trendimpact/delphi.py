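"""Two-round Delphi elicitation: data model, round-1 screening, round-2 aggregation.

Round 1 screens candidate future events: each expert scores the event's
intensity of effect on a 0-10 Likert scale and flags whether the event has
already affected the outcome. An event is retained iff its mean intensity is
at least the cut-off (default 3 — "scored less than 3" is excluded, so a
mean of exactly 3 passes) and no simple majority of experts flagged it as
already affecting the trend.

Round 2 elicits, for each retained event and each horizon year, an
occurrence probability (0-100%) and a signed impact in prevalence
percentage points ('+' raises prevalence, '−' lowers it). Aggregation is
the per-year mean over experts, available-case (missing responses dropped
and logged); probabilities are rescaled to [0, 1] for the simulation engine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Round1Response",
    "Round2Response",
    "Driver",
    "filter_round1",
    "aggregate_round2",
    "participation_summary",
    "load_round1",
    "load_round2",
    "drivers_to_json",
    "drivers_from_json",
    "DEFAULT_CUTOFF",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3.0


@dataclass(frozen=True)
class Round1Response:
    """One expert's round-1 screening of one candidate event."""

    expert_id: str
    event_id: str
    intensity: int
    already_affected: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.intensity, (int, np.integer)) and 0 <= self.intensity <= 10):
            raise ValueError(
                f"intensity must be an integer in 0..10, got {self.intensity!r} "
                f"(expert {self.expert_id}, event {self.event_id})"
            )


@dataclass(frozen=True)
class Round2Response:
    """One expert's round-2 probability/impact elicitation for one event-year."""

    expert_id: str
    event_id: str
    year: int
    probability: float  # percent, 0-100
    impact: float  # signed prevalence change, percentage points

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 100.0:
            raise ValueError(
                f"probability must be in [0, 100], got {self.probability!r} "
                f"(expert {self.expert_id}, event {self.event_id}, year {self.year})"
            )


@dataclass(frozen=True)
class Driver:
    """An aggregated future event: yearly occurrence probability and signed impact.

    ``yearly_probability`` maps each horizon year to the panel-mean occurrence
    probability on the [0, 1] scale; ``yearly_impact`` maps each year to the
    panel-mean signed impact in prevalence percentage points. ``direction`` is
    "positive" (raises prevalence) or "negative" (lowers it) and must agree
    with the sign of every yearly impact.
    """

    event_id: str
    name: str
    direction: str
    yearly_probability: Mapping[int, float]
    yearly_impact: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"direction must be positive/negative, got {self.direction!r}")
        for year, p in self.yearly_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"probability for {self.event_id}/{year} must be in [0,1], got {p!r}"
                )
        sign = 1.0 if self.direction == "positive" else -1.0
        for year, imp in self.yearly_impact.items():
            if sign * imp < 0:
                raise ValueError(
                    f"impact sign for {self.event_id}/{year} ({imp}) contradicts "
                    f"direction {self.direction!r}"
                )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.yearly_probability))

    def probability_array(self, horizon: Sequence[int]) -> np.ndarray:
        try:
            return np.array([self.yearly_probability[int(y)] for y in horizon], dtype=float)
        except KeyError as exc:
            raise ValueError(
                f"driver {self.event_id!r} has no probability for horizon year {exc}"
            ) from exc

    def impact_array(self, horizon: Sequence[int]) -> np.ndarray:
        try:
            return np.array([self.yearly_impact[int(y)] for y in horizon], dtype=float)
        except KeyError as exc:
            raise ValueError(
                f"driver {self.event_id!r} has no impact for horizon year {exc}"
            ) from exc


def filter_round1(
    responses: Iterable[Round1Response], cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Apply round-1 retention rules; returns per-event verdicts.

    An event is retained iff its mean Likert intensity is >= ``cutoff`` and
    the already-affected flags do not reach a simple majority of its
    respondents.

    Returns a DataFrame indexed by event_id with columns ``mean_intensity``,
    ``n_responses``, ``already_affected_share``, ``retained``.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("no round-1 responses")
    df = pd.DataFrame(
        {
            "event_id": [r.event_id for r in responses],
            "intensity": [r.intensity for r in responses],
            "already_affected": [bool(r.already_affected) for r in responses],
        }
    )
    grouped = df.groupby("event_id").agg(
        mean_intensity=("intensity", "mean"),
        n_responses=("intensity", "size"),
        already_affected_share=("already_affected", "mean"),
    )
    grouped["retained"] = (grouped["mean_intensity"] >= cutoff) & (
        grouped["already_affected_share"] <= 0.5
    )
    return grouped.sort_index()


def aggregate_round2(
    responses: Iterable[Round2Response],
    horizon: Sequence[int],
    names: Mapping[str, str] | None = None,
    allow_mixed_sign: bool = False,
) -> list[Driver]:
    """Aggregate round-2 responses into per-event Driver profiles.

    Per event and year: probability is the expert mean divided by 100;
    impact is the signed expert mean in percentage points. Direction is
    inferred from the sign of the mean impacts and, unless
    ``allow_mixed_sign``, must be consistent across years.

    Raises
    ------
    ValueError
        If an event lacks responses for a horizon year, or its mean impacts
        change sign across years (with ``allow_mixed_sign=False``).
    """
    horizon = [int(y) for y in horizon]
    responses = list(responses)
    if not responses:
        raise ValueError("no round-2 responses")
    df = pd.DataFrame(
        {
            "event_id": [r.event_id for r in responses],
            "year": [int(r.year) for r in responses],
            "probability": [r.probability for r in responses],
            "impact": [r.impact for r in responses],
        }
    )
    drivers: list[Driver] = []
    for event_id, event_df in df.groupby("event_id", sort=True):
        means = event_df.groupby("year").agg(
            probability=("probability", "mean"),
            impact=("impact", "mean"),
            n=("impact", "size"),
        )
        missing = [y for y in horizon if y not in means.index]
        if missing:
            raise ValueError(f"event {event_id!r} has no responses for years {missing}")
        n_experts = event_df["expert_id"].nunique() if "expert_id" in event_df else None
        short = means.loc[means["n"] < means["n"].max()]
        for year, row in short.iterrows():
            logger.info(
                "event %s year %d: available-case mean over %d responses",
                event_id, year, int(row["n"]),
            )
        impacts = means.loc[horizon, "impact"].to_numpy()
        nonzero = impacts[impacts != 0]
        if len(nonzero) and np.any(nonzero > 0) and np.any(nonzero < 0):
            if not allow_mixed_sign:
                raise ValueError(
                    f"event {event_id!r} has mixed-sign mean impacts across years; "
                    "pass allow_mixed_sign=True to accept"
                )
            # mixed-sign profile: classify by the sign of the total impact and
            # clamp contradicting years to zero so the Driver invariant holds
            direction = "positive" if impacts.sum() >= 0 else "negative"
            sign = 1.0 if direction == "positive" else -1.0
            impacts = np.where(sign * impacts >= 0, impacts, 0.0)
        else:
            direction = "negative" if np.any(nonzero < 0) else "positive"
        drivers.append(
            Driver(
                event_id=str(event_id),
                name=(names or {}).get(str(event_id), str(event_id)),
                direction=direction,
                yearly_probability={
                    y: float(means.loc[y, "probability"]) / 100.0 for y in horizon
                },
                yearly_impact={y: float(imp) for y, imp in zip(horizon, impacts)},
            )
        )
    return drivers


def participation_summary(round1_ids: Iterable[str], round2_ids: Iterable[str]) -> dict:
    """Panel participation counts and retention rate (percent, 1 dp)."""
    r1 = set(round1_ids)
    r2 = set(round2_ids)
    if not r1 or not r2:
        raise ValueError("expert identifier collections must be non-empty")
    extra = r2 - r1
    if extra:
        logger.warning("round-2 experts absent from round 1: %s", sorted(extra))
    rate = round(100.0 * len(r2) / len(r1), 1)
    return {"n_round1": len(r1), "n_round2": len(r2), "participation_rate": rate}


# -- CSV / JSON interchange ------------------------------------------------

def load_round1(path) -> list[Round1Response]:
    """Read a round-1 CSV: ``expert_id,event_id,intensity,already_affected``."""
    df = pd.read_csv(path)
    return [
        Round1Response(
            expert_id=str(r.expert_id),
            event_id=str(r.event_id),
            intensity=int(r.intensity),
            already_affected=bool(r.already_affected),
        )
        for r in df.itertuples()
    ]


def load_round2(path) -> list[Round2Response]:
    """Read a round-2 CSV: ``expert_id,event_id,year,probability_percent,impact_pp``."""
    df = pd.read_csv(path)
    return [
        Round2Response(
            expert_id=str(r.expert_id),
            event_id=str(r.event_id),
            year=int(r.year),
            probability=float(r.probability_percent),
            impact=float(r.impact_pp),
        )
        for r in df.itertuples()
    ]


def drivers_to_json(drivers: Sequence[Driver], path=None) -> str:
    """Serialize drivers to the engine's JSON contract (probabilities on [0,1])."""
    payload = [
        {
            "event_id": d.event_id,
            "name": d.name,
            "direction": d.direction,
            "years": {
                str(y): {
                    "probability": d.yearly_probability[y],
                    "impact_pp": d.yearly_impact[y],
                }
                for y in d.years
            },
        }
        for d in drivers
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def drivers_from_json(path) -> list[Driver]:
    """Load drivers from the JSON contract written by :func:`drivers_to_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Driver(
            event_id=str(d["event_id"]),
            name=d.get("name", str(d["event_id"])),
            direction=d["direction"],
            yearly_probability={int(y): v["probability"] for y, v in d["years"].items()},
            yearly_impact={int(y): v["impact_pp"] for y, v in d["years"].items()},
        )
        for d in payload
    ]
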