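"""The homologue-series definition: tunable bounds and validity predicates.

A series is an m/z-ordered tuple of peaks whose adjacent differences
obey, simultaneously:

* Δm/z within [dmz_min, dmz_max] — the mass range of plausible
  chemical units at the charges considered;
* ΔRT within [drt_min, drt_max] (drt_min may be negative, e.g. for
  series formed by unit subtractions in meshed families);
* the adjacent mass-defect difference within
  [γ_min·Δm/z − 2ε, γ_max·Δm/z + 2ε], after correcting for the ±1 u
  wrap of defects crossing ±0.5;
* changes of Δm/z between consecutive pairs within ±4ε and changes of
  ΔRT within ±ddrt_max;
* for tuples of length ≥ 4, a cubic smoothing-spline fit RT ~ m/z with
  penalty λ whose R² reaches r2_min.

ε margins are anchored deterministically: the pairwise 2ε margin uses
ε at the lower-m/z peak of the pair, the 4ε margin uses ε at the middle
peak of the three peaks involved.  In absolute-ε mode the anchoring is
immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem import GammaBounds, gamma_bounds
from .peaklist import EpsilonModel, Peak

__all__ = ["DetectionParams", "SeriesContext", "DEFAULT_ELEMENTS"]

DEFAULT_ELEMENTS = frozenset({"C", "H", "N", "O", "S", "Cl", "Br"})


@dataclass(frozen=True)
class DetectionParams:
    """Every user-tunable bound of the series definition.

    Defaults target small-unit surfactant screening: the Δm/z window
    covers the common alkyl (14.016 Th), ethoxylate (44.026 Th) and
    propylene-oxide-like (58.042 Th) units, RT in seconds, and a
    minimum length of five members.
    """

    dmz_min: float = 10.0   # Th
    dmz_max: float = 60.0   # Th
    drt_min: float = 5.0    # RT units (negative allowed)
    drt_max: float = 120.0
    ddrt_max: float = 20.0  # max |change of ΔRT| between consecutive pairs
    n_min: int = 5
    epsilon: EpsilonModel = field(default_factory=EpsilonModel)
    spline_lambda: float = 0.0  # 0 disables smoothing (interpolating fit)
    r2_min: float = 0.9
    elements: frozenset[str] = DEFAULT_ELEMENTS

    def __post_init__(self) -> None:
        if not 0 < self.dmz_min <= self.dmz_max:
            raise ValueError("require 0 < dmz_min <= dmz_max")
        if self.drt_min > self.drt_max:
            raise ValueError("require drt_min <= drt_max")
        if self.ddrt_max < 0:
            raise ValueError("ddrt_max must be non-negative")
        if self.n_min < 3:
            raise ValueError("n_min must be at least 3")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must lie in [0, 1]")
        if self.spline_lambda < 0:
            raise ValueError("spline smoothing parameter must be >= 0")

    def gamma(self) -> GammaBounds:
        return gamma_bounds(self.elements)

    def with_(self, **kwargs) -> "DetectionParams":
        return replace(self, **kwargs)


class SeriesContext:
    """Peak arrays plus parameters shared by the detection stages.

    Holds m/z-sorted coordinate arrays (index order equals peak order)
    and exposes the series-definition predicates on index tuples.  The
    predicates here are the single source of truth: the k-d-tree stage
    uses them to re-validate query candidates and the recombination
    stage to certify merged tuples.
    """

    def __init__(self, peaks: list[Peak], params: DetectionParams):
        self.peaks = peaks
        self.params = params
        self.gamma = params.gamma()
        self.mz = np.array([p.mz for p in peaks], float)
        self.rt = np.array([p.rt for p in peaks], float)
        self.intensity = np.array([p.intensity for p in peaks], float)
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.peaks = [peaks[i] for i in order]
            self.mz = self.mz[order]
            self.rt = self.rt[order]
            self.intensity = self.intensity[order]
        self.defect = self.mz - np.floor(self.mz + 0.5)
        self.eps = np.asarray(params.epsilon.at(self.mz), float)
        self.ids = np.array([p.id for p in self.peaks], int)

    # -- adjacent-pair predicate ------------------------------------------
    def pair_ok(self, lo: int, hi: int) -> bool:
        """Series-definition check for two peaks given by index, lo.mz < hi.mz."""
        p = self.params
        dmz = self.mz[hi] - self.mz[lo]
        if not (p.dmz_min <= dmz <= p.dmz_max):
            return False
        drt = self.rt[hi] - self.rt[lo]
        if not (p.drt_min <= drt <= p.drt_max):
            return False
        lo_b = self.gamma.gamma_min * dmz - 2 * self.eps[lo]
        hi_b = self.gamma.gamma_max * dmz + 2 * self.eps[lo]
        ddef = self.defect[hi] - self.defect[lo]
        # defect wrap: the unwrapped difference may be off by ±1 u
        return any(lo_b <= ddef + s <= hi_b for s in (0.0, -1.0, 1.0))

    # -- three-peak (consecutive pairs) predicate -------------------------
    def interior_ok(self, a: int, b: int, c: int) -> bool:
        """Margins on the change of Δm/z and ΔRT at middle peak b."""
        p = self.params
        d1 = self.mz[b] - self.mz[a]
        d2 = self.mz[c] - self.mz[b]
        if abs(d2 - d1) > 4 * self.eps[b]:
            return False
        r1 = self.rt[b] - self.rt[a]
        r2 = self.rt[c] - self.rt[b]
        return abs(r2 - r1) <= p.ddrt_max

    def tuple_ok(self, idxs: tuple[int, ...], check_spline: bool = True) -> bool:
        """Full validity of an index tuple against the series definition."""
        if len(idxs) < 3 or len(set(idxs)) != len(idxs):
            return False
        if np.any(np.diff(self.mz[list(idxs)]) <= 0):
            return False
        for a, b in zip(idxs, idxs[1:]):
            if not self.pair_ok(a, b):
                return False
        for a, b, c in zip(idxs, idxs[1:], idxs[2:]):
            if not self.interior_ok(a, b, c):
                return False
        if check_spline and len(idxs) >= 4:
            from .recombine import spline_check

            ok, _ = spline_check(
                self.mz[list(idxs)],
                self.rt[list(idxs)],
                self.params.spline_lambda,
                self.params.r2_min,
            )
            return ok
        return True
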