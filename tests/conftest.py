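import numpy as np
import pytest

from isopixel import (
    ControlReference,
    IonCountStack,
    SceneConfig,
    TileGrid,
    generate_root_tip_scene,
    simulate_counts,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def control():
    return ControlReference(at13c_pct=1.07, at15n_pct=0.37, n=322)


def make_stack(rng, shape=(16, 16), p_c=0.011, p_n=0.05, m_c2=400.0, m_cn=800.0,
               **meta) -> IonCountStack:
    """Poisson stack simulated from homogeneous true fractions."""
    counts = {
        "12C": rng.poisson(2 * m_c2 * (1 - p_c), shape),
        "13C": rng.poisson(2 * m_c2 * p_c, shape),
        "12C12C": rng.poisson(m_c2 * (1 - p_c) ** 2, shape),
        "13C12C": rng.poisson(m_c2 * 2 * p_c * (1 - p_c), shape),
        "12C14N": rng.poisson(m_cn * (1 - p_n), shape),
        "12C15N": rng.poisson(m_cn * p_n, shape),
        "31P": rng.poisson(5.0, shape),
        "SE": rng.poisson(m_cn / 2, shape),
    }
    kwargs = dict(pixel_size_um=70.0 / 512.0, dwell_ms=13.5)
    kwargs.update(meta)
    return IonCountStack(counts=counts, **kwargs)


@pytest.fixture
def homogeneous_stack(rng):
    return make_stack(rng)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene + simulated 2x2 tile mosaic shared across tests."""
    cfg = SceneConfig(shape=(184, 184), cell_size_px=12, n_hyphae=25, seed=7)
    truth = generate_root_tip_scene(cfg)
    grid = TileGrid(rows=2, cols=2, tile_px=96, overlap_px=8)
    tiles = simulate_counts(truth, grid, seed=11)
    return truth, grid, tiles
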