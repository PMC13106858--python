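import numpy as np
import pytest

import plaqueniche as pn


@pytest.fixture(scope="session")
def unit_scale():
    return pn.PixelScale(1.0)


@pytest.fixture(scope="session")
def small_field():
    """6 disk plaques in a 512 µm window at 1 µm/px, with distance field."""
    _, field, _ = pn.simulate_field(n_plaques=6, seed=0)
    return field


@pytest.fixture(scope="session")
def two_type_spec():
    panel = [f"g{i}" for i in range(20)]
    types = [
        pn.CellTypeSpec("tcell", tuple(panel[:5]), spatial_rule="plaque_adjacent"),
        pn.CellTypeSpec("microglia", tuple(panel[5:10])),
    ]
    return panel, types


def brute_force_distance(mask, points_rc, scale_um=1.0):
    """O(N*M) reference: min distance from each point to any plaque pixel."""
    fg = np.argwhere(mask > 0)
    out = np.full(len(points_rc), np.inf)
    for i, (r, c) in enumerate(points_rc):
        if len(fg):
            out[i] = np.sqrt(((fg - (r, c)) ** 2).sum(axis=1)).min()
    return out * scale_um
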