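"""A 4-dimensional k-d tree for axis-aligned range queries over peaks.

Each peak is embedded as a 4-vector

    a = (m/z, Δm − γ_min·m/z, Δm − γ_max·m/z, RT)

where Δm is the mass defect of the peak's m/z.  Dimensions 2 and 3
rectify the γ-bounded mass-defect slopes so that the feasible successor
region of a peak becomes an axis-aligned box, which a k-d tree answers
with subtree pruning instead of a full scan.

The tree splits on the median element, cycling the splitting dimension
a1→a2→a3→a4 from the root; median ties break on the lower peak index
and even-sized partitions take the lower middle element, so builds are
deterministic.  Boxes are closed on every dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import GammaBounds, mass_defect

__all__ = ["RangeBox", "embed", "embed_arrays", "PeakKDTree"]

_NDIM = 4


@dataclass(frozen=True)
class RangeBox:
    """Closed axis-aligned box in the 4-d embedding space."""

    lo: tuple[float, float, float, float]
    hi: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.lo) != _NDIM or len(self.hi) != _NDIM:
            raise ValueError("bounds must be 4-vectors")
        for a, b in zip(self.lo, self.hi):
            if a > b:
                raise ValueError(f"lower bound {a} exceeds upper bound {b}")

    def shifted(self, offset: float, dims: tuple[int, ...] = (1, 2)) -> "RangeBox":
        """Box translated by ``offset`` on the given dimensions."""
        lo = list(self.lo)
        hi = list(self.hi)
        for d in dims:
            lo[d] += offset
            hi[d] += offset
        return RangeBox(tuple(lo), tuple(hi))


def embed(mz: float, rt: float, gamma: GammaBounds) -> tuple[float, float, float, float]:
    """Embed one peak; Δm is the mass defect of its m/z."""
    dm = mass_defect(mz)
    return (mz, dm - gamma.gamma_min * mz, dm - gamma.gamma_max * mz, rt)


def embed_arrays(mz: np.ndarray, rt: np.ndarray, gamma: GammaBounds) -> np.ndarray:
    """Vectorized embedding of N peaks into an (N, 4) array."""
    mz = np.asarray(mz, float)
    dm = mz - np.floor(mz + 0.5)
    return np.column_stack(
        [mz, dm - gamma.gamma_min * mz, dm - gamma.gamma_max * mz, np.asarray(rt, float)]
    )


class PeakKDTree:
    """Static 4-d tree over embedded peaks, queried with closed boxes."""

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, float)
        if points.ndim != 2 or (len(points) and points.shape[1] != _NDIM):
            raise ValueError("points must be an (N, 4) array")
        self.points = points
        n = len(points)
        self._idx = np.empty(n, dtype=np.intp)     # point index at node
        self._left = np.full(n, -1, dtype=np.intp)
        self._right = np.full(n, -1, dtype=np.intp)
        self._n_nodes = 0
        self._root = self._build(np.arange(n, dtype=np.intp), 0) if n else -1

    def _build(self, idxs: np.ndarray, depth: int) -> int:
        dim = depth % _NDIM
        # sort by (coordinate, index): ties on the split value break on
        # the lower peak index; lower middle element for even sizes
        order = np.lexsort((idxs, self.points[idxs, dim]))
        idxs = idxs[order]
        mid = (len(idxs) - 1) // 2
        node = self._n_nodes
        self._n_nodes += 1
        self._idx[node] = idxs[mid]
        if mid > 0:
            self._left[node] = self._build(idxs[:mid], depth + 1)
        if mid + 1 < len(idxs):
            self._right[node] = self._build(idxs[mid + 1 :], depth + 1)
        return node

    def query_box(self, box: RangeBox) -> list[int]:
        """Indices of all points inside the closed box, ascending order."""
        if self._root < 0:
            return []
        lo = np.asarray(box.lo, float)
        hi = np.asarray(box.hi, float)
        out: list[int] = []
        stack = [(self._root, 0)]
        pts = self.points
        while stack:
            node, depth = stack.pop()
            i = self._idx[node]
            p = pts[i]
            dim = depth % _NDIM
            v = p[dim]
            if np.all(lo <= p) and np.all(p <= hi):
                out.append(int(i))
            left = self._left[node]
            right = self._right[node]
            # left subtree holds coordinates <= v, right holds >= v
            if left >= 0 and lo[dim] <= v:
                stack.append((left, depth + 1))
            if right >= 0 and hi[dim] >= v:
                stack.append((right, depth + 1))
        out.sort()
        return out

    def __len__(self) -> int:
        return len(self.points)
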