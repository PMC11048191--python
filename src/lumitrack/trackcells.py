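"""Two-session cell tracking by coordinates.

Cells found at the same coordinates in both imaging sessions are *tracked*;
"same coordinates" is operationalised as a one-to-one match within a
tolerance radius.  The default matcher computes the globally optimal
assignment — maximise the number of within-radius pairs, then minimise the
total matched distance — which coincides with mutual-nearest-neighbour
pairing on sparse fields but is well defined and order-independent in
general.  The tallies follow the operational definitions: displaced =
first-image cells minus tracked; lost = first-image minus second-image
count, clamped at zero with an explicit "gained" counter for the degenerate
case where cells appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .quantify import Detection

__all__ = [
    "TrackRecord",
    "FateCounts",
    "match_cells",
    "tally_fates",
    "tracked_fold",
    "tracks_to_frame",
]


@dataclass(frozen=True)
class TrackRecord:
    det_t0: int
    det_t1: Optional[int]
    distance: Optional[float]


@dataclass(frozen=True)
class FateCounts:
    n_t0: int
    n_t1: int
    tracked: int
    lost: int
    displaced: int
    gained: int


def _coords(dets: Sequence[Detection]) -> np.ndarray:
    return np.array([d.centroid for d in dets], dtype=float).reshape(-1, 2)


def _match_optimal(
    p0: np.ndarray, p1: np.ndarray, ids0, ids1, radius: float
) -> List[TrackRecord]:
    n0, n1 = len(p0), len(p1)
    if n0 == 0:
        return []
    if n1 == 0:
        return [TrackRecord(i, None, None) for i in ids0]
    d = np.hypot(
        p0[:, None, 0] - p1[None, :, 0], p0[:, None, 1] - p1[None, :, 1]
    )
    feasible = d <= radius
    # cost larger than any feasible total forces the solver to maximise the
    # number of feasible pairs before minimising distance
    big = radius * (min(n0, n1) + 1) * 10.0 + 1.0
    cost = np.where(feasible, d, big)
    rows, cols = linear_sum_assignment(cost)
    partner = {int(r): int(c) for r, c in zip(rows, cols) if feasible[r, c]}
    records = []
    for i in range(n0):
        j = partner.get(i)
        if j is None:
            records.append(TrackRecord(ids0[i], None, None))
        else:
            records.append(TrackRecord(ids0[i], ids1[j], float(d[i, j])))
    return records


def _match_mutual(
    p0: np.ndarray, p1: np.ndarray, ids0, ids1, radius: float
) -> List[TrackRecord]:
    """Single-pass mutual-nearest-neighbour pairing within the radius.

    A pair is matched iff each member is the other's nearest neighbour and
    their distance is within the radius.  More conservative than the
    optimal assignment: a detection whose nearest neighbour is claimed by a
    closer partner stays unmatched rather than being re-assigned.
    """
    n0, n1 = len(p0), len(p1)
    if n0 == 0:
        return []
    if n1 == 0:
        return [TrackRecord(i, None, None) for i in ids0]
    tree1 = cKDTree(p1)
    d01, j01 = tree1.query(p0, distance_upper_bound=radius)
    tree0 = cKDTree(p0)
    _, i10 = tree0.query(p1, distance_upper_bound=radius)
    records = []
    for i in range(n0):
        j = j01[i]
        if np.isfinite(d01[i]) and j < n1 and i10[j] == i:
            records.append(TrackRecord(ids0[i], ids1[j], float(d01[i])))
        else:
            records.append(TrackRecord(ids0[i], None, None))
    return records


def match_cells(
    dets_t0: Sequence[Detection],
    dets_t1: Sequence[Detection],
    match_radius: float = 15.0,
    method: str = "optimal",
) -> List[TrackRecord]:
    """One-to-one coordinate matching of detections between the two sessions.

    Returns one record per t0 detection (sorted by id); unmatched records
    carry ``det_t1=None``.  ``method="optimal"`` (default) solves the
    max-matches / min-total-distance assignment restricted to pairs within
    ``match_radius``; ``method="mutual"`` keeps only mutual
    nearest-neighbour pairs, which is more conservative against chance
    coincidences on dense fields.  Both are deterministic and independent
    of input order.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    d0 = sorted(dets_t0, key=lambda d: d.det_id)
    d1 = sorted(dets_t1, key=lambda d: d.det_id)
    ids0 = [d.det_id for d in d0]
    ids1 = [d.det_id for d in d1]
    p0, p1 = _coords(d0), _coords(d1)
    if method == "optimal":
        return _match_optimal(p0, p1, ids0, ids1, match_radius)
    if method == "mutual":
        return _match_mutual(p0, p1, ids0, ids1, match_radius)
    raise ValueError(f"unknown matching method {method!r}")


def tally_fates(
    records: Sequence[TrackRecord], n_t0: int, n_t1: int
) -> FateCounts:
    """Tracked / lost / displaced / gained tallies from match records.

    tracked = matched records; displaced = n_t0 - tracked;
    lost = max(n_t0 - n_t1, 0); gained = max(n_t1 - n_t0, 0).
    """
    tracked = sum(1 for r in records if r.det_t1 is not None)
    if tracked > n_t0 or tracked > n_t1:
        raise ValueError("more matches than detections")
    return FateCounts(
        n_t0=n_t0,
        n_t1=n_t1,
        tracked=tracked,
        lost=max(n_t0 - n_t1, 0),
        displaced=n_t0 - tracked,
        gained=max(n_t1 - n_t0, 0),
    )


def tracked_fold(
    counts_condition: FateCounts, counts_baseline: FateCounts
) -> float:
    """Ratio of tracked-cell counts, condition over baseline."""
    if counts_baseline.tracked <= 0:
        raise ZeroDivisionError("baseline has no tracked cells")
    return counts_condition.tracked / counts_baseline.tracked


def tracks_to_frame(records: Sequence[TrackRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                det_t0=r.det_t0,
                det_t1=r.det_t1 if r.det_t1 is not None else pd.NA,
                distance=r.distance if r.distance is not None else np.nan,
            )
            for r in records
        ],
        columns=["det_t0", "det_t1", "distance"],
    )
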