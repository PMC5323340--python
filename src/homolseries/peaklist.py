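"""Peak-table input/output and the m/z measurement-uncertainty model.

A picked LC-HRMS peak is a triple (m/z, RT, intensity).  Peaks are read
from delimited text, sorted by increasing m/z and given stable integer
ids 1..N in that order, which makes every downstream output
deterministic for identical input.  ``EpsilonModel`` captures the
maximum ± m/z measurement error ε, either as an absolute width in Th or
proportional to m/z (ppm).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .recombine import SeriesTuple

__all__ = ["Peak", "EpsilonModel", "read_peaks", "write_series", "peaks_to_frame"]

_REQUIRED = ("mz", "rt", "intensity")


@dataclass(frozen=True)
class Peak:
    """One picked LC-HRMS signal."""

    id: int
    mz: float  # Th
    rt: float  # user units, consistent within a run
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class EpsilonModel:
    """Maximum ± m/z measurement error, absolute (Th) or ppm."""

    mode: str = "absolute"
    value: float = 0.002

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "ppm"):
            raise ValueError(f"mode must be 'absolute' or 'ppm', got {self.mode!r}")
        if self.value <= 0:
            raise ValueError("epsilon value must be positive")

    def at(self, mz: float | np.ndarray) -> float | np.ndarray:
        """ε in Th at a given m/z (vectorizes over arrays)."""
        if self.mode == "absolute":
            return self.value if np.isscalar(mz) else np.full_like(np.asarray(mz, float), self.value)
        return mz * self.value * 1e-6


def epsilon_at(model: EpsilonModel, mz: float) -> float:
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return float(model.at(mz))


class PeakTableError(ValueError):
    """Malformed peak table (missing columns or non-numeric cells)."""


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.read_text() else ""
    best, count = ",", -1
    for cand in (",", "\t", ";"):
        if head.count(cand) > count:
            best, count = cand, head.count(cand)
    return best


def read_peaks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[Peak]:
    """Read a delimited peak table into m/z-sorted :class:`Peak` records.

    ``column_map`` maps the canonical names mz/rt/intensity to the
    column names actually present.  Rows are sorted by increasing m/z
    (ties keep file order) and ids assigned 1..N in that order.
    Non-numeric cells raise with their line numbers; duplicate rows are
    retained as distinct peaks.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    frame.columns = [c.strip() for c in frame.columns]
    names = {k: (column_map or {}).get(k, k) for k in _REQUIRED}
    missing = [names[k] for k in _REQUIRED if names[k] not in frame.columns]
    if missing:
        raise PeakTableError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )
    numeric = {}
    for key in _REQUIRED:
        col = pd.to_numeric(frame[names[key]], errors="coerce")
        bad = frame.index[col.isna() & frame[names[key]].notna()]
        empty = frame.index[frame[names[key]].isna()]
        bad = bad.union(empty)
        if len(bad):
            # +2: header line plus 1-based counting
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise PeakTableError(
                f"{path}: non-numeric or empty {names[key]!r} cell(s) at line(s) {lines}"
            )
        numeric[key] = col.to_numpy(float)
    order = np.argsort(numeric["mz"], kind="stable")
    return [
        Peak(
            id=i + 1,
            mz=float(numeric["mz"][j]),
            rt=float(numeric["rt"][j]),
            intensity=float(numeric["intensity"][j]),
        )
        for i, j in enumerate(order)
    ]


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [p.id for p in peaks],
            "mz": [p.mz for p in peaks],
            "rt": [p.rt for p in peaks],
            "intensity": [p.intensity for p in peaks],
        }
    )


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    peaks_to_frame(peaks).to_csv(path, index=False, float_format="%.6f")


def write_series(
    series: Sequence["SeriesTuple"],
    summary_path: str | Path,
    assignments_path: str | Path,
) -> None:
    """Write a per-series summary table and a long peak↔series table.

    A peak that belongs to k series appears k times in the assignment
    table; both files carry headers even when no series were found.
    """
    summary_rows = []
    assign_rows = []
    for s in series:
        summary_rows.append(
            {
                "series_id": s.series_id,
                "length": len(s.peak_ids),
                "mean_dmz": s.mean_dmz,
                "mean_drt": s.mean_drt,
                "r2": s.r2 if s.r2 is not None else np.nan,
                "peak_ids": ";".join(str(i) for i in s.peak_ids),
            }
        )
        for pos, pid in enumerate(s.peak_ids, start=1):
            assign_rows.append(
                {"peak_id": pid, "series_id": s.series_id, "position": pos}
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=["series_id", "length", "mean_dmz", "mean_drt", "r2", "peak_ids"],
    )
    assignments = pd.DataFrame(
        assign_rows, columns=["peak_id", "series_id", "position"]
    )
    summary.to_csv(summary_path, index=False, float_format="%.6f",
                   quoting=csv.QUOTE_MINIMAL)
    assignments.to_csv(assignments_path, index=False)
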