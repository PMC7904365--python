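import numpy as np
import pytest

from oct_edema import default_spec, enhance, generate_phantom, segment
from oct_edema.segment import SBGFRLSConfig


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * np.sum(a & b) / denom if denom else 1.0


@pytest.fixture(scope="session")
def phantom_pair():
    """Reference speckled phantom (seed 0)."""
    return generate_phantom(default_spec(seed=0))


@pytest.fixture(scope="session")
def phantom_batch():
    """Ten seeded phantoms with their enhanced images and segmentations.

    Shared across the simulation-based tests so the end-to-end pipeline runs
    once per seed; each entry also carries segmentations from three distinct
    rectangular initializations.
    """
    batch = []
    for seed in range(10):
        pair = generate_phantom(default_spec(seed=seed))
        enhanced = enhance(pair.image)
        results = {
            margin: segment(enhanced, SBGFRLSConfig(init_margin=margin))
            for margin in (5, 10, 25)
        }
        batch.append({"pair": pair, "enhanced": enhanced, "results": results})
    return batch
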