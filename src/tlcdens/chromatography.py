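"""Retention factors, lane assignment and Rf identity checks.

The retention factor of a spot is the distance it travelled from the origin
line divided by the distance travelled by the solvent front,

    Rf = (origin_row - centroid_row) / (origin_row - front_row),

a dimensionless number in [0, 1].  Distances are measured on the resampled
crop, using the moment centroid of the spot.  Rf values are carried at full
precision internally and rounded to two decimals only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyLaneError, GeometryError, UndefinedStatError
from .pipeline import Spot

__all__ = ["RfResult", "LaneMap", "compute_rf", "assign_lanes",
           "select_principal", "rf_match"]


@dataclass(frozen=True)
class RfResult:
    rf: float
    distance_spot: float   # pixels from origin row up to the spot centroid
    distance_front: float  # pixels from origin row up to the solvent front

    def __post_init__(self) -> None:
        if not (0.0 <= self.distance_spot <= self.distance_front):
            raise GeometryError(
                f"spot distance {self.distance_spot} outside [0, {self.distance_front}]"
            )


@dataclass
class LaneMap:
    """Grouping of spots into vertical lanes by centroid column."""

    lane_centers: list[float]
    assignment: dict[int, int]  # spot index -> lane index
    gap_threshold: float

    def lanes(self, spots: list[Spot]) -> list[list[Spot]]:
        """Spots grouped per lane, in lane order."""
        groups: list[list[Spot]] = [[] for _ in self.lane_centers]
        for idx, lane in self.assignment.items():
            groups[lane].append(spots[idx])
        return groups


def compute_rf(spot: Spot, origin_row: float, front_row: float) -> RfResult:
    """Retention factor of a spot given the plate's reference rows.

    Row indices increase downward, so the front row is numerically smaller
    than the origin row and a larger migration distance means a smaller
    centroid row.
    """
    if not origin_row > front_row:
        raise GeometryError(
            f"origin_row ({origin_row}) must lie below front_row ({front_row})"
        )
    row = spot.centroid[0]
    if not (front_row - 0.5 <= row <= origin_row + 0.5):
        raise GeometryError(
            f"spot centroid row {row} outside the development region "
            f"[{front_row}, {origin_row}]"
        )
    d_front = float(origin_row - front_row)
    d_spot = float(np.clip(origin_row - row, 0.0, d_front))
    rf = d_spot / d_front
    spot.rf = rf
    return RfResult(rf=rf, distance_spot=d_spot, distance_front=d_front)


def assign_lanes(spots: list[Spot], gap_threshold: float) -> LaneMap:
    """1-D single-linkage clustering of centroid columns.

    Spots are sorted by column; a new lane starts whenever the gap to the
    previous centroid exceeds ``gap_threshold``.  A sensible default threshold
    is crop_width / (2 * expected_lanes).
    """
    if not spots:
        raise EmptyLaneError("cannot assign lanes with no spots")
    if gap_threshold <= 0:
        raise GeometryError(f"gap_threshold must be > 0, got {gap_threshold}")
    order = sorted(range(len(spots)), key=lambda i: spots[i].centroid[1])
    assignment: dict[int, int] = {}
    lane_cols: list[list[float]] = []
    prev_col: float | None = None
    for idx in order:
        col = spots[idx].centroid[1]
        if prev_col is None or col - prev_col > gap_threshold:
            lane_cols.append([])
        lane_cols[-1].append(col)
        assignment[idx] = len(lane_cols) - 1
        prev_col = col
    centers = [float(np.mean(cols)) for cols in lane_cols]
    for idx, lane in assignment.items():
        spots[idx].lane = lane
    return LaneMap(lane_centers=centers, assignment=assignment,
                   gap_threshold=float(gap_threshold))


def select_principal(lane_spots: list[Spot]) -> Spot:
    """The principal spot of a lane: largest AUC, ties broken by larger
    area, then by the spot nearer the solvent front (smaller row)."""
    if not lane_spots:
        raise EmptyLaneError("empty lane has no principal spot")
    return max(lane_spots, key=lambda s: (s.auc, s.area_px, -s.centroid[0]))


def rf_match(sample_rf: float, standard_rf: float,
             tolerance_frac: float = 0.10) -> bool:
    """True when the sample Rf deviates from the standard's by at most
    ``tolerance_frac`` (relative deviation, boundary inclusive)."""
    if standard_rf == 0:
        raise UndefinedStatError("relative Rf deviation undefined for standard_rf = 0")
    if not (0.0 <= sample_rf <= 1.0 and 0.0 < standard_rf <= 1.0):
        raise GeometryError("Rf values must lie in [0, 1]")
    if tolerance_frac <= 0:
        raise GeometryError("tolerance_frac must be > 0")
    return abs(sample_rf - standard_rf) / standard_rf <= tolerance_frac
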