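"""Outcome labelling from treadmill recovery series.

The study splits injured animals into favorable and adverse groups by the
dynamics of their recovery on a treadmill (speed ceiling 50 m/min, tests on
days 7-60) without quantifying the rule.  To make the grouping reproducible
this module uses an explicit two-criterion rule: an animal is favorable when
its day-60 maximum speed reaches a threshold (default 30 m/min, 60% of the
ceiling) OR its least-squares recovery slope over the test days reaches a
slope threshold (default 0.3 m/min per day).  Both thresholds are
configurable; the boundary case (exactly at a threshold) counts as
favorable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OutcomeConfig:
    speed_threshold: float = 30.0  # m/min at day 60
    slope_threshold: float = 0.3  # m/min per day
    required_days: tuple[int, ...] = (7, 60)


@dataclass(frozen=True)
class OutcomeLabel:
    label: str  # "favorable" or "adverse"
    final_speed: float  # m/min at the last required day
    slope: float  # least-squares m/min per day
    animal_id: Optional[str] = None


def classify_outcome(
    series: pd.DataFrame,
    config: OutcomeConfig = OutcomeConfig(),
    animal_id: Optional[str] = None,
) -> OutcomeLabel:
    """Label one animal's treadmill series favorable or adverse.

    ``series`` needs columns ``day`` and ``max_speed`` and must cover the
    configured required days (default 7 and 60).  The label is a pure
    function of the series and the config.
    """
    for col in ("day", "max_speed"):
        if col not in series.columns:
            raise ValueError(f"series missing column {col!r}")
    series = series.sort_values("day")
    days = series["day"].to_numpy(dtype=float)
    speeds = series["max_speed"].to_numpy(dtype=float)
    missing = set(config.required_days) - set(int(d) for d in days)
    if missing:
        raise ValueError(f"series missing required test days: {sorted(missing)}")
    final_day = max(config.required_days)
    final_speed = float(speeds[days == final_day][0])
    slope = float(np.polyfit(days, speeds, 1)[0])
    favorable = final_speed >= config.speed_threshold or slope >= config.slope_threshold
    return OutcomeLabel(
        label="favorable" if favorable else "adverse",
        final_speed=final_speed,
        slope=slope,
        animal_id=animal_id,
    )


def classify_cohort(
    series_table: pd.DataFrame, config: OutcomeConfig = OutcomeConfig()
) -> pd.DataFrame:
    """Classify every animal in a long table (animal_id, day, max_speed)."""
    rows = []
    for animal, sub in series_table.groupby("animal_id", sort=True):
        lab = classify_outcome(sub, config, animal_id=str(animal))
        rows.append(
            {
                "animal_id": animal,
                "label": lab.label,
                "final_speed": lab.final_speed,
                "slope": lab.slope,
            }
        )
    return pd.DataFrame(rows)
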