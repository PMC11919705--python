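"""Place-preference behaviour: cage geometry, occupancy and correctness.

The test arena is a 1 m x 1 m box partitioned into five regions: four square
corner compartments (c1..c4) and the interconnecting center space. During
conditioning one corner (c3 by convention) is paired with amphetamine; at
test the animal roams freely and its trajectory is scored by the
*correctness score* — the fraction of total corner dwell time spent in the
conditioned corner. With four equivalent corners the chance level is 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

REGIONS = ("c1", "c2", "c3", "c4", "center")
CORNERS = ("c1", "c2", "c3", "c4")


@dataclass(frozen=True)
class CageGeometry:
    """Square box with four square corner regions and a center region.

    Corners are axis-aligned squares of side ``corner_size``: c1 at (low x,
    low y), c2 at (high x, low y), c3 at (high x, high y), c4 at (low x,
    high y). The five regions tile the box without overlap.
    """

    side: float = 1.0
    corner_size: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ParameterError("cage side must be positive")
        if not (0 < self.corner_size and 2 * self.corner_size <= self.side):
            raise ParameterError("need 0 < 2*corner_size <= side")

    def region_of(self, x: float, y: float) -> str:
        """Region containing (x, y); boundary points go to the corner."""
        c, s = self.corner_size, self.side
        low_x, high_x = x <= c, x >= s - c
        low_y, high_y = y <= c, y >= s - c
        if low_x and low_y:
            return "c1"
        if high_x and low_y:
            return "c2"
        if high_x and high_y:
            return "c3"
        if low_x and high_y:
            return "c4"
        return "center"

    def region_area(self, region: str) -> float:
        if region in CORNERS:
            return self.corner_size**2
        if region == "center":
            return self.side**2 - 4 * self.corner_size**2
        raise ParameterError(f"unknown region {region!r}")

    def center_point(self) -> tuple[float, float]:
        return self.side / 2.0, self.side / 2.0


@dataclass
class Trajectory:
    """Timestamped positions (seconds, meters) for one test entry."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    entry_label: str = "first"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise DataError("t, x, y must have equal length")
        if len(self.t) == 0:
            raise DataError("trajectory is empty")
        if np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def reversed(self) -> "Trajectory":
        tt = self.t[-1] - self.t[::-1]
        return Trajectory(tt, self.x[::-1], self.y[::-1], self.entry_label)

    def save(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def load(cls, path: str | Path, entry_label: str = "first") -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t"].values, df["x"].values, df["y"].values, entry_label)


@dataclass
class RegionOccupancy:
    """Per-region dwell times in seconds."""

    dwell: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.dwell.values()))

    @property
    def corner_total(self) -> float:
        return float(sum(self.dwell.get(c, 0.0) for c in CORNERS))


def occupancy(
    traj: Trajectory, geom: CageGeometry, tolerance: float = 1e-6
) -> RegionOccupancy:
    """Dwell time per region: each inter-sample interval is attributed to the
    region containing the earlier sample's position."""
    if (
        np.any(traj.x < -tolerance)
        or np.any(traj.x > geom.side + tolerance)
        or np.any(traj.y < -tolerance)
        or np.any(traj.y > geom.side + tolerance)
    ):
        raise DataError("trajectory positions fall outside the cage box")
    dwell = {r: 0.0 for r in REGIONS}
    dts = np.diff(traj.t)
    for i, dt in enumerate(dts):
        dwell[geom.region_of(traj.x[i], traj.y[i])] += float(dt)
    return RegionOccupancy(dwell=dwell)


def correctness_score(occ: RegionOccupancy, conditioned: str = "c3") -> float:
    """Fraction of the total corner time spent in the conditioned corner.

    Returns NaN (undefined) when the animal never visits a corner.
    """
    if conditioned not in CORNERS:
        raise ParameterError(f"conditioned corner must be one of {CORNERS}")
    total = occ.corner_total
    if total <= 0:
        return float("nan")
    return occ.dwell.get(conditioned, 0.0) / total


def usv_behaviour_association(
    usv_counts: Sequence[float], scores: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Spearman association between training USV counts and
    correctness scores (raw scale; the rank test is scale-invariant)."""
    from .stats import spearman_test

    usv_counts = np.asarray(usv_counts, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(usv_counts) != len(scores):
        raise DataError("usv_counts and scores must be paired")
    if len(scores) < 4:
        raise DataError("need at least 4 paired observations")
    return spearman_test(usv_counts, scores)


def score_table(
    trajectories: Mapping[str, Trajectory],
    geom: CageGeometry,
    conditioned: str = "c3",
) -> pd.DataFrame:
    """Per-animal occupancy and correctness table."""
    rows = []
    for animal, traj in trajectories.items():
        occ = occupancy(traj, geom)
        row = {"animal_id": animal, "entry": traj.entry_label}
        row.update({f"dwell_{r}": occ.dwell[r] for r in REGIONS})
        row["correctness"] = correctness_score(occ, conditioned)
        rows.append(row)
    return pd.DataFrame(rows)
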