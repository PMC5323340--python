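from __future__ import annotations

import numpy as np
import pytest

from homolseries import DetectionParams, EpsilonModel, Peak


@pytest.fixture
def loose_params() -> DetectionParams:
    """Wide bounds so random peak clouds actually produce pairs/triplets."""
    return DetectionParams(
        dmz_min=5.0,
        dmz_max=80.0,
        drt_min=-100.0,
        drt_max=200.0,
        ddrt_max=100.0,
        n_min=3,
        epsilon=EpsilonModel("absolute", 0.005),
    )


def random_peaks(rng: np.random.Generator, n: int,
                 mz_range=(100.0, 600.0), rt_range=(60.0, 1200.0)) -> list[Peak]:
    mz = np.sort(rng.uniform(*mz_range, n))
    rt = rng.uniform(*rt_range, n)
    return [Peak(i + 1, float(mz[i]), float(rt[i]), 1.0) for i in range(n)]
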