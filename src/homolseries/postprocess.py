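"""Blank voting and monoisotopic voting on detected series.

Blank subtraction asks, per series peak, whether a procedural-blank
measurement shows signal at the same place: a sample peak *fails* if a
picked blank peak lies within a peak-centered m/z × RT window and is
more intense than ``intensity_factor`` times the sample peak.  A
majority rule (fraction of failing peaks >= 0.5 by default) then tags
the whole series as blank.

Monoisotopic voting consumes externally supplied isotopologue-group
annotations: each annotated peak carries its 1-based m/z rank within
its isotopologue group, and a series is called monoisotopic when the
modal rank over its annotated peaks equals 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .peaklist import Peak
from .recombine import SeriesTuple

__all__ = [
    "IsotopologueAnnotation",
    "BlankVerdict",
    "blank_flag",
    "monoisotopic_flag",
]


@dataclass(frozen=True)
class IsotopologueAnnotation:
    """Peak membership and m/z rank within an isotopologue group."""

    peak_id: int
    group_id: int
    mz_rank: int  # 1 = lowest-m/z (monoisotopic) member of the group

    def __post_init__(self) -> None:
        if self.mz_rank < 1:
            raise ValueError("mz_rank must be >= 1")


@dataclass(frozen=True)
class BlankVerdict:
    series_id: int
    is_blank: bool
    failing_fraction: float
    failing_peaks: tuple[int, ...]


def blank_flag(
    series: Sequence[SeriesTuple],
    sample_peaks: Sequence[Peak],
    blank_peaks: Sequence[Peak],
    mz_tol: float,
    rt_tol: float,
    intensity_factor: float = 0.1,
    majority: float = 0.5,
) -> tuple[list[BlankVerdict], dict[int, bool]]:
    """Vote every series blank/non-blank against a blank peak list.

    Returns per-series verdicts and a per-peak flag map (True = peak
    failed the blank check).  An empty blank list passes every peak.
    """
    if mz_tol < 0 or rt_tol < 0:
        raise ValueError("tolerances must be non-negative")
    by_id = {p.id: p for p in sample_peaks}
    blanks = sorted(blank_peaks, key=lambda p: p.mz)
    bmz = [b.mz for b in blanks]

    import bisect

    def peak_fails(p: Peak) -> bool:
        lo = bisect.bisect_left(bmz, p.mz - mz_tol)
        hi = bisect.bisect_right(bmz, p.mz + mz_tol)
        for b in blanks[lo:hi]:
            if abs(b.rt - p.rt) <= rt_tol and b.intensity > intensity_factor * p.intensity:
                return True
        return False

    peak_flags: dict[int, bool] = {}
    verdicts = []
    for s in series:
        failing = []
        for pid in s.peak_ids:
            if pid not in peak_flags:
                peak_flags[pid] = peak_fails(by_id[pid])
            if peak_flags[pid]:
                failing.append(pid)
        frac = len(failing) / len(s.peak_ids)
        verdicts.append(
            BlankVerdict(s.series_id, frac >= majority, frac, tuple(failing))
        )
    return verdicts, peak_flags


def monoisotopic_flag(
    series: Sequence[SeriesTuple],
    annotations: Iterable[IsotopologueAnnotation] | Mapping[int, int],
) -> dict[int, str]:
    """Modal-rank vote per series: 'monoisotopic', 'not_monoisotopic',
    'tie' (modal tie including rank 1, counted as monoisotopic) or
    'undetermined' (no annotated peak).

    Unannotated peaks are excluded from the mode.
    """
    if isinstance(annotations, Mapping):
        rank_of = dict(annotations)
    else:
        rank_of = {a.peak_id: a.mz_rank for a in annotations}
    out: dict[int, str] = {}
    for s in series:
        ranks = [rank_of[pid] for pid in s.peak_ids if pid in rank_of]
        if not ranks:
            out[s.series_id] = "undetermined"
            continue
        counts = Counter(ranks)
        top = max(counts.values())
        modes = {r for r, c in counts.items() if c == top}
        if modes == {1}:
            out[s.series_id] = "monoisotopic"
        elif 1 in modes:
            out[s.series_id] = "tie"  # resolved in favour of monoisotopic
        else:
            out[s.series_id] = "not_monoisotopic"
    return out


def is_monoisotopic(verdict: str) -> bool:
    """Collapse the verdict string to a boolean (ties count as True)."""
    return verdict in ("monoisotopic", "tie")
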