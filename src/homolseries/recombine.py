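"""Stage 2: recursive recombination of triplets into longer series tuples.

Two n-tuples that overlap in all but their first/last member merge into
an (n+1)-tuple; n-tuples that extended at least once are dropped from
their own length class.  Merging repeats until no longer tuples form.
Retention-time smoothness across a tuple is enforced by a cubic
smoothing spline RT ~ m/z whose coefficient of determination must reach
``r2_min``; finally, sub-tuples formed by a regular omission of peaks
from retained longer tuples are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaklist import Peak
from .seriesdef import DetectionParams, SeriesContext

__all__ = [
    "SeriesTuple",
    "smoothing_spline_fit",
    "spline_check",
    "merge_step",
    "filter_subtuples",
    "detect_series",
]

IndexTuple = tuple[int, ...]


@dataclass(frozen=True)
class SeriesTuple:
    """A detected homologue-series candidate.

    ``peak_ids`` are ordered by increasing m/z; ``mean_dmz`` /
    ``mean_drt`` are means over adjacent differences; ``r2`` is the
    smoothing-spline fit statistic (None for length-3 tuples, where the
    spline is not fitted).
    """

    series_id: int
    peak_ids: tuple[int, ...]
    mean_dmz: float
    mean_drt: float
    r2: float | None = None

    def __len__(self) -> int:
        return len(self.peak_ids)


def smoothing_spline_fit(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Fitted values of the natural cubic smoothing spline.

    Minimizes sum (y_i - g(x_i))^2 + lam * int g''(t)^2 dt over natural
    cubic splines with knots at the strictly increasing x.  The fitted
    values are (I + lam*K)^{-1} y with K = Q R^{-1} Q^T built from the
    knot spacings; lam = 0 interpolates.  Valid for n >= 3 (and handled
    for n >= 4 by callers, where the penalty is identifiable).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3 or lam == 0:
        return y.copy()
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    h = np.diff(x)
    m = n - 2
    Q = np.zeros((n, m))
    for j in range(m):
        Q[j, j] = 1.0 / h[j]
        Q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
        Q[j + 2, j] = 1.0 / h[j + 1]
    R = np.zeros((m, m))
    for j in range(m):
        R[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < m:
            R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    return np.linalg.solve(np.eye(n) + lam * K, y)


def spline_check(
    mz: np.ndarray, rt: np.ndarray, lam: float, r2_min: float
) -> tuple[bool, float | None]:
    """Smoothness test of RT over m/z for one tuple.

    Returns (passed, r2).  Tuples shorter than four peaks skip the
    check (the ΔΔRT margin already constrains them); constant-RT tuples
    pass by the SS_total = 0 convention.
    """
    n = len(mz)
    if n < 4:
        return True, None
    rt = np.asarray(rt, float)
    ss_tot = float(np.sum((rt - rt.mean()) ** 2))
    if ss_tot == 0.0:
        return True, 1.0
    fitted = smoothing_spline_fit(mz, rt, lam)
    r2 = 1.0 - float(np.sum((rt - fitted) ** 2)) / ss_tot
    return r2 >= r2_min, r2


def merge_step(
    s_n: set[IndexTuple], ctx: SeriesContext
) -> tuple[set[IndexTuple], set[IndexTuple]]:
    """One recombination round: (n+1)-tuples plus the unextended n-tuples.

    Tuples x and y merge when x's last n-1 peaks equal y's first n-1,
    or vice versa; every overlapping orientation is tried and an
    n-tuple may join several different (n+1)-tuples.  Merged tuples
    must pass the smoothing-spline check; tuples that extended at least
    once are removed from their length class.
    """
    by_prefix: dict[IndexTuple, list[IndexTuple]] = {}
    for t in s_n:
        by_prefix.setdefault(t[:-1], []).append(t)
    extended: set[IndexTuple] = set()
    s_next: set[IndexTuple] = set()
    p = ctx.params
    for x in s_n:
        for y in by_prefix.get(x[1:], ()):
            merged = x + (y[-1],)
            ok, _ = spline_check(
                ctx.mz[list(merged)], ctx.rt[list(merged)],
                p.spline_lambda, p.r2_min,
            )
            if ok:
                s_next.add(merged)
                extended.add(x)
                extended.add(y)
    return s_next, s_n - extended


def _regular_subtuples(t: IndexTuple) -> set[IndexTuple]:
    """All arithmetic index subsequences of t with step >= 2, length >= 3."""
    n = len(t)
    out: set[IndexTuple] = set()
    for k in range(2, (n - 1) // 2 + 1):
        for r in range(k):
            lane = t[r::k]
            for m in range(3, len(lane) + 1):
                for off in range(len(lane) - m + 1):
                    out.add(tuple(lane[off : off + m]))
    return out


def filter_subtuples(
    sets_by_len: dict[int, set[IndexTuple]],
) -> dict[int, set[IndexTuple]]:
    """Drop tuples that are a regular omission of a retained longer tuple.

    A tuple is redundant when its peaks appear in a retained tuple of
    length >= 5 at indices forming an arithmetic progression with step
    k >= 2 (any offset); irregularly spaced sub-tuples are kept.
    """
    redundant: set[IndexTuple] = set()
    for n, tuples in sets_by_len.items():
        if n >= 5:
            for t in tuples:
                redundant |= _regular_subtuples(t)
    return {
        n: {t for t in tuples if t not in redundant}
        for n, tuples in sets_by_len.items()
    }


def detect_series(
    peaks: list[Peak],
    params: DetectionParams,
    stats: dict | None = None,
) -> list[SeriesTuple]:
    """Full two-stage detection: triplets, recombination, filtering.

    Returns all retained tuples of length >= n_min as
    :class:`SeriesTuple` records referencing peak ids, sorted by first
    peak id then length, with series ids 1..K in that order.  If a
    ``stats`` dict is supplied it is filled with per-stage funnel
    counts (peaks, triplets, retained tuples per length, series).
    """
    from .triplets import find_triplet_indices

    ctx = SeriesContext(peaks, params)
    current = find_triplet_indices(ctx)
    if stats is not None:
        stats["n_peaks"] = len(peaks)
        stats["n_triplets"] = len(current)
    retained: dict[int, set[IndexTuple]] = {}
    n = 3
    while current:
        current, kept = merge_step(current, ctx)
        if kept:
            retained[n] = kept
        n += 1
    retained = filter_subtuples(retained)
    if stats is not None:
        stats["retained_per_length"] = {k: len(v) for k, v in sorted(retained.items())}

    results: list[SeriesTuple] = []
    for length in sorted(retained):
        if length < params.n_min:
            continue
        for t in retained[length]:
            idx = list(t)
            mzs = ctx.mz[idx]
            rts = ctx.rt[idx]
            _, r2 = spline_check(mzs, rts, params.spline_lambda, params.r2_min)
            results.append(
                SeriesTuple(
                    series_id=0,
                    peak_ids=tuple(int(ctx.ids[i]) for i in t),
                    mean_dmz=float(np.mean(np.diff(mzs))),
                    mean_drt=float(np.mean(np.diff(rts))),
                    r2=r2,
                )
            )
    results.sort(key=lambda s: (s.peak_ids[0], len(s.peak_ids), s.peak_ids))
    if stats is not None:
        stats["n_series"] = len(results)
    return [
        SeriesTuple(i + 1, s.peak_ids, s.mean_dmz, s.mean_drt, s.r2)
        for i, s in enumerate(results)
    ]
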