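"""Series pairing: intersection angles, SOM-ready vectors, prevalence.

A peak may belong to several series; every unordered pair of series
sharing at least one peak is extracted.  The pair's *intersection
angle* θ measures how superjacent the two series are in the RT vs m/z
plane: each series is summarized by the vector of its range-scaled mean
ΔRT and mean Δm/z, and θ is the angle between the two vectors (θ = 0
means fully superjacent; a histogram-derived default of θ < 0.08π
separates superjacent from meshed pairs).  For clustering with external
SOM tools, each pair also yields a 4-vector of uncertainty-scaled mean
differences, ordered so the series with larger mean Δm/z comes first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .recombine import SeriesTuple

__all__ = [
    "SeriesPair",
    "find_pairs",
    "intersection_angle",
    "pair_vector",
    "compute_pairs",
    "classify_superjacent",
    "delta_mz_prevalence",
    "DEFAULT_THETA_THRESHOLD",
]

DEFAULT_THETA_THRESHOLD = 0.08 * math.pi


@dataclass(frozen=True)
class SeriesPair:
    """Two peak-sharing series, x carrying the larger mean Δm/z."""

    series_x: SeriesTuple
    series_y: SeriesTuple
    shared_peaks: frozenset[int]
    theta: float | None = None

    def __post_init__(self) -> None:
        if not self.shared_peaks:
            raise ValueError("paired series must share at least one peak")
        if self.series_x.mean_dmz < self.series_y.mean_dmz:
            raise ValueError("series_x must carry the larger mean dmz")


def find_pairs(series: Sequence[SeriesTuple]) -> list[SeriesPair]:
    """Every unordered pair of series sharing >= 1 peak id, once each."""
    owner: dict[int, list[int]] = {}
    for i, s in enumerate(series):
        for pid in s.peak_ids:
            owner.setdefault(pid, []).append(i)
    seen: set[tuple[int, int]] = set()
    pairs: list[SeriesPair] = []
    for members in owner.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                key = (members[a], members[b])
                if key in seen:
                    continue
                seen.add(key)
                sa, sb = series[key[0]], series[key[1]]
                shared = frozenset(sa.peak_ids) & frozenset(sb.peak_ids)
                if sa.mean_dmz < sb.mean_dmz:
                    sa, sb = sb, sa
                pairs.append(SeriesPair(sa, sb, shared))
    pairs.sort(key=lambda p: (p.series_x.series_id, p.series_y.series_id))
    return pairs


def intersection_angle(
    pair: SeriesPair, c_drt: float, c_dmz: float
) -> float:
    """Angle θ ∈ [0, π] between the scaled (mean ΔRT, mean Δm/z) vectors.

    ``c_drt`` and ``c_dmz`` are the ranges of mean ΔRT and mean Δm/z
    over all series of the sample; the cosine is clamped to [-1, 1]
    before the arccos.
    """
    if c_drt <= 0 or c_dmz <= 0:
        raise ValueError("scale constants must be positive")
    ux = (pair.series_x.mean_drt / c_drt, pair.series_x.mean_dmz / c_dmz)
    uy = (pair.series_y.mean_drt / c_drt, pair.series_y.mean_dmz / c_dmz)
    dot = ux[0] * uy[0] + ux[1] * uy[1]
    norm = math.hypot(*ux) * math.hypot(*uy)
    if norm == 0:
        raise ValueError("zero-norm series vector")
    return math.acos(max(-1.0, min(1.0, dot / norm)))


def pair_vector(
    pair: SeriesPair, c_hat_drt: float, c_hat_dmz: float
) -> tuple[float, float, float, float]:
    """SOM input vector of uncertainty-scaled mean differences.

    Components: (mean ΔRT_x/ĉ_ΔRT, mean Δm/z_x/ĉ_Δm/z, mean ΔRT_y/...,
    mean Δm/z_y/...), with x the larger-Δm/z series by construction.
    """
    if c_hat_drt <= 0 or c_hat_dmz <= 0:
        raise ValueError("scale constants must be positive")
    x, y = pair.series_x, pair.series_y
    return (
        x.mean_drt / c_hat_drt,
        x.mean_dmz / c_hat_dmz,
        y.mean_drt / c_hat_drt,
        y.mean_dmz / c_hat_dmz,
    )


def compute_pairs(series: Sequence[SeriesTuple]) -> list[SeriesPair]:
    """Pairs with θ filled in, scales taken as ranges over all series.

    Degenerate ranges (all series identical in a coordinate) fall back
    to a unit scale so the angle stays defined.
    """
    pairs = find_pairs(series)
    if not pairs:
        return []
    drts = [s.mean_drt for s in series]
    dmzs = [s.mean_dmz for s in series]
    c_drt = max(drts) - min(drts) or 1.0
    c_dmz = max(dmzs) - min(dmzs) or 1.0
    return [
        SeriesPair(
            p.series_x, p.series_y, p.shared_peaks,
            theta=intersection_angle(p, c_drt, c_dmz),
        )
        for p in pairs
    ]


def classify_superjacent(
    pairs: Sequence[SeriesPair],
    theta_threshold: float = DEFAULT_THETA_THRESHOLD,
) -> tuple[list[SeriesPair], list[SeriesPair]]:
    """Partition pairs into (superjacent, meshed) by θ < threshold."""
    superjacent = [p for p in pairs if p.theta is not None and p.theta < theta_threshold]
    meshed = [p for p in pairs if p not in superjacent]
    return superjacent, meshed


def delta_mz_prevalence(
    per_sample_series: Mapping[str, Sequence[SeriesTuple]],
    window: float = 5e-3,
) -> pd.DataFrame:
    """Cross-sample prevalence of series mean Δm/z values.

    For every distinct mean Δm/z observed in any sample, count the
    samples containing at least one series whose mean Δm/z lies within
    ±``window`` Th of it.  Returns a frame with columns (dmz,
    sample_count) sorted by dmz.
    """
    if not per_sample_series:
        raise ValueError("need at least one sample")
    sample_values = {
        name: np.sort([s.mean_dmz for s in series_list])
        for name, series_list in per_sample_series.items()
    }
    centers = np.unique(np.concatenate([v for v in sample_values.values()] or [np.array([])]))
    counts = []
    for c in centers:
        k = sum(
            1
            for vals in sample_values.values()
            if len(vals)
            and np.searchsorted(vals, c - window, "left")
            < np.searchsorted(vals, c + window, "right")
        )
        counts.append(k)
    return pd.DataFrame({"dmz": centers, "sample_count": counts})
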