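import numpy as np
import pytest
from shapely.geometry import box

from greenexp import Grid, Zone, ZoneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_green():
    """8x8 fractional grid, 100 m cells, deterministic values."""
    vals = np.linspace(0.0, 1.0, 64).reshape(8, 8)
    return Grid(values=vals, cell_size=100.0)


@pytest.fixture
def full_zone():
    """Single rectangular zone covering an 8x8 grid of 100 m cells."""
    return ZoneSet([Zone("z", box(0.0, -800.0, 800.0, 0.0),
                         {"hemisphere": "N"})])


def pairwise_gini(values, weights):
    """O(n^2) weighted Gini oracle: sum w_i w_j |v_i - v_j| / (2 W^2 mu)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    mu = (w * v).sum() / W
    if mu == 0:
        return 0.0
    diff = np.abs(np.subtract.outer(v, v))
    return float((w[:, None] * w[None, :] * diff).sum() / (2 * W**2 * mu))


def brute_focal(values, cell_size, radius_m):
    """Brute-force circular focal mean (all cells valid, renormalized)."""
    rows, cols = values.shape
    out = np.zeros_like(values, dtype=float)
    r2 = radius_m**2 * (1 + 1e-12)
    n = int(np.floor(radius_m / cell_size + 1e-9))
    for i in range(rows):
        for j in range(cols):
            acc, cnt = 0.0, 0
            for di in range(-n, n + 1):
                for dj in range(-n, n + 1):
                    if (di * cell_size) ** 2 + (dj * cell_size) ** 2 > r2:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols:
                        acc += values[ii, jj]
                        cnt += 1
            out[i, j] = acc / cnt
    return out


def brute_edge_length(fg, cell_size):
    """Count exposed foreground cell edges by direct scan; length in m."""
    rows, cols = fg.shape
    edges = 0
    for i in range(rows):
        for j in range(cols):
            if not fg[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if not (0 <= ii < rows and 0 <= jj < cols) or not fg[ii, jj]:
                    edges += 1
    return edges * cell_size
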