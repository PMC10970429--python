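"""Discrimination-learning outcomes from CognitionWall entry counts.

Mice earn food rewards by entering a three-door wall through the left
(correct) entrance.  Learning over a 48-h session is summarized by a single
index per animal:

    LI = (CE_D2 - IE_D2) / TE_D2 - (CE_D1 - IE_D1) / TE_D1

where CE/IE/TE are correct, incorrect and total entry counts on each day.
The continuous index is banded into a categorical 5-point learning level by
standard deviations from the cohort mean, and animals are clustered on the
index to flag behavioral outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

__all__ = [
    "DailyEntryCounts",
    "LearningOutcome",
    "learning_index",
    "learning_level",
    "outcomes_from_entry_logs",
    "cluster_animals",
]


@dataclass(frozen=True)
class DailyEntryCounts:
    """Aggregated CognitionWall entries for one animal on one day.

    CE counts left-entrance (correct) entries, IE counts middle/right
    (incorrect) entries; CE + IE must equal TE.
    """

    animal_id: str
    day: int
    CE: int
    IE: int
    TE: int

    def __post_init__(self) -> None:
        if self.CE < 0 or self.IE < 0 or self.TE < 0:
            raise ValueError("entry counts must be nonnegative")
        if self.CE + self.IE != self.TE:
            raise ValueError(
                f"CE + IE must equal TE (got {self.CE}+{self.IE} != {self.TE})"
            )

    @property
    def daily_fraction(self) -> float:
        """(CE - IE) / TE for this day; undefined when TE = 0."""
        if self.TE == 0:
            raise ZeroDivisionError(
                f"learning fraction undefined: animal {self.animal_id} "
                f"day {self.day} has zero total entries"
            )
        return (self.CE - self.IE) / self.TE


@dataclass(frozen=True)
class LearningOutcome:
    """Continuous learning index (bounded by [-2, 2]) and 5-point level."""

    animal_id: str
    index: float
    level: int


def learning_index(day1: DailyEntryCounts, day2: DailyEntryCounts) -> float:
    """Learning growth from day 1 to day 2.

    Returns ``(CE2-IE2)/TE2 - (CE1-IE1)/TE1``.  Raises if either day has
    zero total entries (the index is undefined, not zero) or if the two
    records belong to different animals.
    """
    if day1.animal_id != day2.animal_id:
        raise ValueError(
            f"day records belong to different animals: "
            f"{day1.animal_id!r} vs {day2.animal_id!r}"
        )
    return day2.daily_fraction - day1.daily_fraction


def learning_level(index: float, cohort_mean: float, cohort_sd: float) -> int:
    """Band a learning index into a 1-5 level by SDs from the cohort mean.

    z < -2 -> 1; -2 <= z < -1 -> 2; -1 <= z < 0 -> 3; 0 <= z < 1 -> 4;
    z >= 1 -> 5.  Level >= 4 iff index >= mean, which is the positive
    state used downstream for ROC prediction.
    """
    if cohort_sd <= 0:
        raise ValueError("cohort_sd must be positive")
    z = (index - cohort_mean) / cohort_sd
    edges = (-2.0, -1.0, 0.0, 1.0)
    return 1 + int(np.searchsorted(edges, z, side="right"))


def outcomes_from_entry_logs(entry_logs: pd.DataFrame) -> pd.DataFrame:
    """Compute per-animal learning index and level from a long entry table.

    ``entry_logs`` needs columns animal_id, day, CE, IE, TE with days 1 and 2
    per animal.  The level banding uses the cohort mean/SD of the computed
    indices.  Returns a DataFrame indexed by animal_id with columns
    ``index`` and ``level``.
    """
    required = {"animal_id", "day", "CE", "IE", "TE"}
    missing = required - set(entry_logs.columns)
    if missing:
        raise ValueError(f"entry log missing columns: {sorted(missing)}")

    indices = {}
    for animal, rows in entry_logs.groupby("animal_id", sort=True):
        by_day = {int(r.day): r for r in rows.itertuples()}
        if set(by_day) != {1, 2}:
            raise ValueError(f"animal {animal!r} needs exactly days 1 and 2")
        days = {
            d: DailyEntryCounts(str(animal), d, int(r.CE), int(r.IE), int(r.TE))
            for d, r in by_day.items()
        }
        indices[str(animal)] = learning_index(days[1], days[2])

    out = pd.DataFrame({"index": pd.Series(indices)})
    out.index.name = "animal_id"
    mean = float(out["index"].mean())
    sd = float(out["index"].std(ddof=1))
    if sd <= 0:
        # Degenerate cohort (all indices equal): everyone is "normal".
        out["level"] = 4
    else:
        out["level"] = [learning_level(v, mean, sd) for v in out["index"]]
    return out


def cluster_animals(outcomes: pd.DataFrame) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering of animals on learning index; flag outliers.

    An animal is flagged when it is the last singleton merged into the
    tree, i.e. the root merge joins that single animal to everything else
    at a strictly greater height than any earlier merge.  Returns the
    scipy linkage matrix and a boolean Series of flags.

    ``outcomes`` must contain an ``index`` column (from
    :func:`outcomes_from_entry_logs`) and at least 3 animals.
    """
    if len(outcomes) < 3:
        raise ValueError("need at least 3 animals to cluster")
    values = outcomes["index"].to_numpy(dtype=float)[:, None]
    Z = linkage(pdist(values, metric="euclidean"), method="average")
    flags = pd.Series(False, index=outcomes.index, name="outlier")

    n = len(outcomes)
    root = Z[-1]
    prev_height = Z[-2, 2] if n > 2 else 0.0
    for child in (int(root[0]), int(root[1])):
        if child < n and root[2] > prev_height:
            flags.iloc[child] = True
    return Z, flags
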