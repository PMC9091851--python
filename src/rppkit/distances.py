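"""Trajectory similarity measures on RPPs: DTW, edit distance and LCSS.

An RPP is treated as a two-dimensional trajectory — a short ordered sequence
of (quadrant position, porosity) points.  Missing quadrants are dropped
(their positions retained on the surviving points), which is what lets these
measures tolerate incomplete profiles with up to two missing values.

* DTW: minimal sum of Euclidean point-to-point distances over monotone
  warping paths covering both sequences (unconstrained, unnormalized).
* Edit distance: Levenshtein dynamic program where two points match (cost 0)
  iff both coordinate differences are within ``eps``; mismatch, insertion
  and deletion each cost 1.
* LCSS: longest common subsequence under the same eps-matching, maximized
  over a symmetric grid of candidate translations of the second trajectory
  in both dimensions; similarity = count / min(len1, len2), distance =
  1 - similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import InvalidInputError, RPPTrajectory, is_analysable

__all__ = [
    "TrajectoryPoints",
    "DistanceMatrix",
    "dtw",
    "edit_distance",
    "lcss",
    "distance_matrix",
    "DEFAULT_EPS",
    "DEFAULT_N_TRANSLATIONS",
]

#: Default matching tolerance (porosity points / quadrant positions).
DEFAULT_EPS = 5.0
#: Default number of candidate LCSS translations per dimension (per sign).
DEFAULT_N_TRANSLATIONS = 20


@dataclass(frozen=True)
class TrajectoryPoints:
    """A trajectory as ordered 2-D points with strictly increasing positions."""

    points: tuple[tuple[float, float], ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not (1 <= len(self.points) <= 4):
            raise InvalidInputError("trajectory must hold 1-4 points")
        pos = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InvalidInputError("positions must be strictly increasing")
        object.__setattr__(
            self,
            "points",
            tuple((float(p), float(v)) for p, v in self.points),
        )

    @classmethod
    def from_trajectory(cls, traj: RPPTrajectory) -> "TrajectoryPoints":
        """Build points from an RPP by dropping missing entries."""
        arr = traj.as_array()
        pts = tuple(
            (float(i + 1), float(v)) for i, v in enumerate(arr) if not np.isnan(v)
        )
        if not pts:
            raise InvalidInputError("trajectory has no measured points")
        return cls(points=pts, source=traj.element_id)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with their element ids."""

    ids: tuple[str, ...]
    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise InvalidInputError("distance matrix shape must match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise InvalidInputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise InvalidInputError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise InvalidInputError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def dtw(t1: TrajectoryPoints, t2: TrajectoryPoints) -> float:
    """Dynamic time warping distance between two 2-D trajectories.

    Minimal total Euclidean distance over monotone warping paths that start
    at the first point pair, end at the last, and advance by one point in
    either or both sequences per step.
    """
    a, b = t1.as_array(), t2.as_array()
    n, m = len(a), len(b)
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    return float(acc[-1, -1])


def _matches(p: np.ndarray, q: np.ndarray, eps: float) -> bool:
    return abs(p[0] - q[0]) <= eps and abs(p[1] - q[1]) <= eps


def edit_distance(
    t1: TrajectoryPoints, t2: TrajectoryPoints, eps: float = DEFAULT_EPS
) -> int:
    """Minimum number of point edits making the trajectories equivalent."""
    if eps < 0:
        raise InvalidInputError("eps must be >= 0")
    a, b = t1.as_array(), t2.as_array()
    n, m = len(a), len(b)
    d = np.zeros((n + 1, m + 1), dtype=int)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 0 if _matches(a[i - 1], b[j - 1], eps) else 1
            d[i, j] = min(d[i - 1, j - 1] + sub, d[i - 1, j] + 1, d[i, j - 1] + 1)
    return int(d[n, m])


def _lcs_count(a: np.ndarray, b: np.ndarray, eps: float) -> int:
    n, m = len(a), len(b)
    d = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if _matches(a[i - 1], b[j - 1], eps):
                d[i, j] = d[i - 1, j - 1] + 1
            else:
                d[i, j] = max(d[i - 1, j], d[i, j - 1])
    return int(d[n, m])


def lcss(
    t1: TrajectoryPoints,
    t2: TrajectoryPoints,
    eps: float = DEFAULT_EPS,
    n_translations: int = DEFAULT_N_TRANSLATIONS,
) -> tuple[float, float]:
    """LCSS similarity and distance with 2-D translation search.

    The second trajectory is translated over a symmetric grid of
    ``2 * n_translations + 1`` offsets per dimension spanning +/- the joint
    coordinate range of the two trajectories; the longest eps-matching common
    subsequence over all offsets defines similarity = count / min(|t1|, |t2|)
    and distance = 1 - similarity.  Returns ``(similarity, distance)``.
    """
    if eps < 0:
        raise InvalidInputError("eps must be >= 0")
    if n_translations < 1:
        raise InvalidInputError("n_translations must be >= 1")
    a, b = t1.as_array(), t2.as_array()
    both = np.vstack([a, b])
    spans = both.max(axis=0) - both.min(axis=0)
    best = 0
    offsets = [
        np.linspace(-max(span, eps), max(span, eps), 2 * n_translations + 1)
        for span in spans
    ]
    for dx in offsets[0]:
        for dy in offsets[1]:
            shifted = b + np.array([dx, dy])
            best = max(best, _lcs_count(a, shifted, eps))
            if best == min(len(a), len(b)):
                similarity = 1.0
                return similarity, 0.0
    similarity = best / min(len(a), len(b))
    return float(similarity), float(1.0 - similarity)


def distance_matrix(
    trajs: Sequence[RPPTrajectory],
    method: str = "dtw",
    eps: float = DEFAULT_EPS,
    n_translations: int = DEFAULT_N_TRANSLATIONS,
) -> tuple[DistanceMatrix, list[str]]:
    """Pairwise distance matrix over analysable trajectories.

    Non-analysable trajectories (fewer than two measured points) are excluded
    and returned as the rejection list.  Returns ``(matrix, rejected_ids)``.
    """
    kept, rejected = [], []
    for t in trajs:
        (kept if is_analysable(t) else rejected).append(t)
    if len(kept) < 2:
        raise InvalidInputError("need at least two analysable trajectories")
    pts = [TrajectoryPoints.from_trajectory(t) for t in kept]
    ids = tuple(t.element_id for t in kept)
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate element ids in trajectory list")
    n = len(pts)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "dtw":
                d = dtw(pts[i], pts[j])
            elif method == "ed":
                d = float(edit_distance(pts[i], pts[j], eps))
            elif method == "lcss":
                d = lcss(pts[i], pts[j], eps, n_translations)[1]
            else:
                raise InvalidInputError(f"unknown method {method!r}")
            vals[i, j] = vals[j, i] = d
    return (
        DistanceMatrix(ids=ids, values=vals, method=method),
        [t.element_id for t in rejected],
    )
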