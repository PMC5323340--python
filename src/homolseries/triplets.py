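"""Stage 1: k-d-tree extraction of all feasible series 3-tuples.

Every peak is taken in turn as the middle member of candidate triplets.
Two closed boxes in the 4-d embedding space describe where feasible
predecessors (subspace L, lower m/z) and successors (subspace H, higher
m/z) can lie; the k-d tree returns the candidates and the full series
predicates then certify each (l, center, h) combination.  Because the
L query of one center is exactly the H query of its predecessor, the
implementation enumerates valid adjacent *pairs* through H queries from
every peak and joins pairs on the shared middle peak — the triplet set
is identical.
"""

from __future__ import annotations

import math

from .kdtree import PeakKDTree, RangeBox, embed_arrays
from .peaklist import Peak
from .seriesdef import DetectionParams, SeriesContext

__all__ = ["subspace_boxes", "find_triplets", "find_triplet_indices", "find_pair_indices"]

_INF = math.inf


def subspace_boxes(
    center: Peak, params: DetectionParams, gamma=None
) -> tuple[list[RangeBox], list[RangeBox]]:
    """Predecessor (L) and successor (H) query boxes for one center peak.

    Each side is a union of up to three boxes: the base box plus copies
    shifted by ±1 u on the two mass-defect dimensions wherever the
    center's defect plus the γ-bounded change could cross ±0.5 and wrap.
    """
    gamma = gamma or params.gamma()
    a1, a2, a3, a4 = embed_arrays([center.mz], [center.rt], gamma)[0]
    eps = float(params.epsilon.at(center.mz))
    p = params
    h_base = RangeBox(
        (a1 + p.dmz_min, a2 - 2 * eps, -_INF, a4 + p.drt_min),
        (a1 + p.dmz_max, _INF, a3 + 2 * eps, a4 + p.drt_max),
    )
    l_base = RangeBox(
        (a1 - p.dmz_max, -_INF, a3 - 2 * eps, a4 - p.drt_max),
        (a1 - p.dmz_min, a2 + 2 * eps, _INF, a4 - p.drt_min),
    )
    defect = center.mz - math.floor(center.mz + 0.5)
    reach_up = gamma.gamma_max * p.dmz_max + 2 * eps
    reach_dn = gamma.gamma_min * p.dmz_max - 2 * eps
    h_boxes = [h_base]
    l_boxes = [l_base]
    # successors may wrap: stored defect = true defect ∓ 1
    if defect + reach_up >= 0.5:
        h_boxes.append(h_base.shifted(-1.0))
    if defect + reach_dn <= -0.5:
        h_boxes.append(h_base.shifted(+1.0))
    # predecessors wrap mirrored
    if defect - reach_dn >= 0.5:
        l_boxes.append(l_base.shifted(-1.0))
    if defect - reach_up <= -0.5:
        l_boxes.append(l_base.shifted(+1.0))
    return l_boxes, h_boxes


def _h_boxes_for_index(ctx: SeriesContext, i: int, vec) -> list[RangeBox]:
    p = ctx.params
    g = ctx.gamma
    eps = float(ctx.eps[i])
    a1, a2, a3, a4 = vec
    base = RangeBox(
        (a1 + p.dmz_min, a2 - 2 * eps, -_INF, a4 + p.drt_min),
        (a1 + p.dmz_max, _INF, a3 + 2 * eps, a4 + p.drt_max),
    )
    boxes = [base]
    defect = ctx.defect[i]
    if defect + g.gamma_max * p.dmz_max + 2 * eps >= 0.5:
        boxes.append(base.shifted(-1.0))
    if defect + g.gamma_min * p.dmz_max - 2 * eps <= -0.5:
        boxes.append(base.shifted(+1.0))
    return boxes


def find_pair_indices(ctx: SeriesContext) -> list[tuple[int, int]]:
    """All index pairs (lo, hi) valid as adjacent series members."""
    n = len(ctx.mz)
    if n == 0:
        return []
    vectors = embed_arrays(ctx.mz, ctx.rt, ctx.gamma)
    tree = PeakKDTree(vectors)
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        candidates: set[int] = set()
        for box in _h_boxes_for_index(ctx, i, vectors[i]):
            candidates.update(tree.query_box(box))
        for j in sorted(candidates):
            if j != i and ctx.pair_ok(i, j):
                pairs.append((i, j))
    return pairs


def find_triplet_indices(ctx: SeriesContext) -> set[tuple[int, int, int]]:
    """All feasible 3-tuples as index triples, duplicate-free."""
    pairs = find_pair_indices(ctx)
    by_middle: dict[int, list[int]] = {}
    by_lower: dict[int, list[int]] = {}
    for lo, hi in pairs:
        by_middle.setdefault(hi, []).append(lo)
        by_lower.setdefault(lo, []).append(hi)
    triplets: set[tuple[int, int, int]] = set()
    for center in by_middle:
        succ = by_lower.get(center)
        if not succ:
            continue
        for lo in by_middle[center]:
            for hi in succ:
                if ctx.interior_ok(lo, center, hi):
                    triplets.add((lo, center, hi))
    return triplets


def find_triplets(
    peaks: list[Peak], params: DetectionParams
) -> set[tuple[int, int, int]]:
    """Feasible triplets as peak-id 3-tuples, ordered by increasing m/z."""
    ctx = SeriesContext(peaks, params)
    return {
        tuple(int(ctx.ids[i]) for i in t) for t in find_triplet_indices(ctx)
    }
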