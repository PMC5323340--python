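"""Independent brute-force oracles used by the test suite.

These re-implement the series-definition predicates and box membership
directly from the definitions (plain arithmetic, no k-d tree, no shared
code path with the detection stages) so stage-1 and the range queries
can be checked against exhaustive enumeration.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_mass_defect(mz: float) -> float:
    return mz - math.floor(mz + 0.5)


def oracle_pair_ok(lo, hi, params, gamma) -> bool:
    """Adjacent-pair predicate applied directly to two peaks (lo.mz < hi.mz)."""
    dmz = hi.mz - lo.mz
    if not (params.dmz_min <= dmz <= params.dmz_max):
        return False
    drt = hi.rt - lo.rt
    if not (params.drt_min <= drt <= params.drt_max):
        return False
    eps = float(params.epsilon.at(lo.mz))
    lo_b = gamma.gamma_min * dmz - 2 * eps
    hi_b = gamma.gamma_max * dmz + 2 * eps
    ddef = oracle_mass_defect(hi.mz) - oracle_mass_defect(lo.mz)
    return any(lo_b <= ddef + s <= hi_b for s in (0.0, 1.0, -1.0))


def brute_force_triplets(peaks, params) -> set[tuple[int, int, int]]:
    """All id triplets satisfying the series definition, by full enumeration."""
    gamma = params.gamma()
    ordered = sorted(peaks, key=lambda p: (p.mz, p.id))
    n = len(ordered)
    succ: dict[int, list[int]] = {i: [] for i in range(n)}
    pred: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if ordered[j].mz > ordered[i].mz and oracle_pair_ok(
                ordered[i], ordered[j], params, gamma
            ):
                succ[i].append(j)
                pred[j].append(i)
    out: set[tuple[int, int, int]] = set()
    for c in range(n):
        eps_c = float(params.epsilon.at(ordered[c].mz))
        for a in pred[c]:
            for b in succ[c]:
                d1 = ordered[c].mz - ordered[a].mz
                d2 = ordered[b].mz - ordered[c].mz
                if abs(d2 - d1) > 4 * eps_c:
                    continue
                r1 = ordered[c].rt - ordered[a].rt
                r2 = ordered[b].rt - ordered[c].rt
                if abs(r2 - r1) > params.ddrt_max:
                    continue
                out.add((ordered[a].id, ordered[c].id, ordered[b].id))
    return out


def linear_scan_box(points: np.ndarray, lo, hi) -> list[int]:
    """Closed-box membership by direct comparison over all points."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    mask = np.all((points >= lo) & (points <= hi), axis=1)
    return sorted(np.nonzero(mask)[0].tolist())
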