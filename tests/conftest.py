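import warnings

import numpy as np
import pytest

from breastmwi import PipelineConfig, run_pipeline
from breastmwi.phantom import (
    benign_preset,
    generate_phantom,
    invasive_preset,
    malignant_preset,
)

warnings.filterwarnings("ignore", message=".*tumour voxels lie outside.*")

SEED = 1


@pytest.fixture(scope="session")
def benign_phantom():
    return generate_phantom(benign_preset(seed=SEED))


@pytest.fixture(scope="session")
def malignant_phantom():
    return generate_phantom(malignant_preset(seed=SEED))


@pytest.fixture(scope="session")
def invasive_phantom():
    return generate_phantom(invasive_preset(seed=SEED))


@pytest.fixture(scope="session")
def benign_result(benign_phantom):
    cfg = PipelineConfig(tumour_class="benign", frequencies_ghz=(6.0,))
    return run_pipeline(cfg, benign_phantom)


@pytest.fixture(scope="session")
def malignant_result(malignant_phantom):
    cfg = PipelineConfig(tumour_class="malignant", frequencies_ghz=(6.0,))
    return run_pipeline(cfg, malignant_phantom)


@pytest.fixture(scope="session")
def invasive_result(invasive_phantom):
    cfg = PipelineConfig(tumour_class="malignant", frequencies_ghz=(6.0,))
    return run_pipeline(cfg, invasive_phantom)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

_NEIGHBOURS_6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
_NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def bfs_flood_fill(data, seed, lo, hi, connectivity=6):
    """Breadth-first flood fill of the intensity window [lo, hi] from seed."""
    data = np.asarray(data)
    offsets = _NEIGHBOURS_6 if connectivity == 6 else _NEIGHBOURS_26
    out = np.zeros(data.shape, dtype=bool)
    if not (lo <= data[tuple(seed)] <= hi):
        return out
    stack = [tuple(seed)]
    out[tuple(seed)] = True
    while stack:
        x, y, z = stack.pop()
        for dx, dy, dz in offsets:
            p = (x + dx, y + dy, z + dz)
            if all(0 <= c < s for c, s in zip(p, data.shape)):
                if not out[p] and lo <= data[p] <= hi:
                    out[p] = True
                    stack.append(p)
    return out


def bfs_components(occ, connectivity=6):
    """BFS connected-component labelling; labels 1..K in raster-scan order."""
    occ = np.asarray(occ).astype(bool)
    offsets = _NEIGHBOURS_6 if connectivity == 6 else _NEIGHBOURS_26
    labels = np.zeros(occ.shape, dtype=np.int32)
    next_label = 1
    for start in zip(*np.nonzero(occ)):
        if labels[start]:
            continue
        labels[start] = next_label
        stack = [start]
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(p, occ.shape)):
                    if occ[p] and not labels[p]:
                        labels[p] = next_label
                        stack.append(p)
        next_label += 1
    return labels
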